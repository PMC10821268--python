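"""G4Hunter-style G-quadruplex propensity scanning of (circular) DNA.

Scoring follows the G4Hunter rule: every base in a run of n consecutive
guanines scores +min(n, 4), every base in a run of n consecutive cytosines
scores -min(n, 4), and A/T/N score 0. A sliding window (default 25 nt) whose
mean absolute score reaches the threshold (default 1.2) flags a
G4-prone site; overlapping qualifying windows are merged into one hit.
Positive window means indicate G-richness on the given strand (hit on +),
negative means indicate C-richness, i.e. a quadruplex on the complement
(hit on -).

Circular sequences (e.g. the mitochondrial genome) are handled natively:
G/C runs, scan windows, hits and feature intervals may all wrap the origin.
Coordinates are 1-based inclusive throughout; a wrapped interval is written
with end < start.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby

import numpy as np
import pandas as pd

__all__ = [
    "CircularSequence",
    "G4Hit",
    "Feature",
    "FeatureTable",
    "HitSummary",
    "base_scores",
    "call_hits",
    "annotate_hits",
    "circular_interval_length",
    "region_extract",
]

_VALID_BASES = frozenset("ACGTN")
FEATURE_CLASSES = ("protein_coding", "rRNA", "tRNA", "D_loop", "other_noncoding")


@dataclass(frozen=True)
class CircularSequence:
    """A DNA sequence, optionally circular. Positions are 1-based inclusive."""

    id: str
    bases: str
    circular: bool = False

    def __post_init__(self):
        if len(self.bases) == 0:
            raise ValueError("empty sequence")
        bad = set(self.bases) - _VALID_BASES
        if bad:
            raise ValueError(f"illegal bases {sorted(bad)} in sequence {self.id!r}")

    def __len__(self) -> int:
        return len(self.bases)

    def reverse_complement(self) -> "CircularSequence":
        comp = str.maketrans("ACGTN", "TGCAN")
        return CircularSequence(self.id, self.bases.translate(comp)[::-1], self.circular)


@dataclass(frozen=True)
class G4Hit:
    """A merged G4-prone interval. ``end < start`` means it wraps the origin."""

    start: int
    end: int
    strand: str
    score: float

    def length(self, L: int) -> int:
        if self.start <= self.end:
            return self.end - self.start + 1
        return L - self.start + 1 + self.end

    def midpoint(self, L: int) -> int:
        half = (self.length(L) - 1) // 2
        return (self.start - 1 + half) % L + 1


@dataclass(frozen=True)
class Feature:
    name: str
    start: int
    end: int
    strand: str
    feature_class: str

    def __post_init__(self):
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(
                f"unknown feature class {self.feature_class!r} for {self.name!r}"
            )

    def contains(self, pos: int) -> bool:
        """Circular containment of a 1-based position."""
        if self.start <= self.end:
            return self.start <= pos <= self.end
        return pos >= self.start or pos <= self.end


@dataclass
class FeatureTable:
    """An ordered list of annotated intervals on a circular genome."""

    features: list

    def class_of(self, pos: int) -> str:
        """Class of the first feature containing ``pos``; intergenic
        positions fall back to ``other_noncoding``."""
        for f in self.features:
            if f.contains(pos):
                return f.feature_class
        return "other_noncoding"

    def in_dloop(self, pos: int) -> bool:
        return any(f.feature_class == "D_loop" and f.contains(pos) for f in self.features)

    def count_class(self, feature_class: str) -> int:
        return sum(f.feature_class == feature_class for f in self.features)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureTable":
        need = {"name", "start", "end", "strand", "class"}
        if not need.issubset(df.columns):
            raise ValueError(f"feature table needs columns {sorted(need)}")
        feats = [
            Feature(str(r["name"]), int(r["start"]), int(r["end"]),
                    str(r["strand"]), str(r["class"]))
            for _, r in df.iterrows()
        ]
        return cls(feats)


@dataclass(frozen=True)
class HitSummary:
    n_total: int
    fraction_protein_coding: float
    fraction_noncoding: float
    fraction_of_noncoding_in_dloop: float
    n_in_dloop: int
    by_class: dict


def base_scores(seq: CircularSequence) -> np.ndarray:
    """Per-base G4Hunter scores: +min(n,4) within a G-run of length n,
    -min(n,4) within a C-run, 0 elsewhere. On circular sequences a run may
    wrap the origin; N breaks runs."""
    s = seq.bases
    L = len(s)
    scores = np.zeros(L, dtype=np.int8)
    runs = []  # (char, start_index, length)
    i = 0
    for ch, grp in groupby(s):
        n = sum(1 for _ in grp)
        runs.append((ch, i, n))
        i += n
    # join a run wrapping the origin (same base at both ends, not one single run)
    if seq.circular and len(runs) > 1 and runs[0][0] == runs[-1][0]:
        ch, _, n_first = runs[0]
        _, start_last, n_last = runs[-1]
        joined = n_first + n_last
        runs[0] = (ch, 0, n_first, joined)
        runs[-1] = (ch, start_last, n_last, joined)
    out = []
    for run in runs:
        ch, start, n = run[0], run[1], run[2]
        eff = run[3] if len(run) == 4 else n
        if ch == "G":
            scores[start : start + n] = min(eff, 4)
        elif ch == "C":
            scores[start : start + n] = -min(eff, 4)
    return scores


def _window_means(scores: np.ndarray, window: int, circular: bool) -> np.ndarray:
    """Mean score of each window start (0-based). Circular scans have L
    starts; linear scans have L - window + 1."""
    if circular:
        ext = np.concatenate([scores, scores[: window - 1]]).astype(float)
    else:
        ext = scores.astype(float)
    c = np.concatenate([[0.0], np.cumsum(ext)])
    return (c[window:] - c[:-window]) / window


def _covered_runs(cov: np.ndarray, circular: bool) -> list:
    """Maximal runs of True in a boolean array, joining across the origin
    when circular. Returns 0-based (start, end) inclusive pairs; a wrapped
    run has end < start."""
    L = cov.size
    if not cov.any():
        return []
    if cov.all():
        return [(0, L - 1)]
    idx = np.flatnonzero(cov)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = idx[np.concatenate([[0], breaks + 1])]
    ends = idx[np.concatenate([breaks, [idx.size - 1]])]
    runs = list(zip(starts.tolist(), ends.tolist()))
    if circular and len(runs) > 1 and runs[0][0] == 0 and runs[-1][1] == L - 1:
        runs[0] = (runs[-1][0], runs[0][1])  # wrap-join
        runs.pop()
    return runs


def _interval_scores(scores: np.ndarray, start0: int, end0: int) -> float:
    if start0 <= end0:
        return float(np.mean(scores[start0 : end0 + 1]))
    return float(np.mean(np.concatenate([scores[start0:], scores[: end0 + 1]])))


def call_hits(
    seq: CircularSequence, window: int = 25, threshold: float = 1.2
) -> list[G4Hit]:
    """Scan with step-1 sliding windows and merge qualifying windows.

    A window qualifies when |mean base score| >= threshold. Overlapping
    qualifying windows of the same sign are merged; the hit covers their
    union, its score is the mean base score over the merged interval and
    its strand is '+' for G-rich (positive) and '-' for C-rich (negative)
    windows. On circular sequences windows wrap the origin and a hit
    spanning the origin is reported once, with end < start.
    """
    L = len(seq)
    if window > L:
        raise ValueError(f"window ({window}) exceeds sequence length ({L})")
    scores = base_scores(seq)
    means = _window_means(scores, window, seq.circular)
    hits: list[G4Hit] = []
    for sign, strand in ((1, "+"), (-1, "-")):
        qualifying = np.flatnonzero(sign * means >= threshold)
        if qualifying.size == 0:
            continue
        cov = np.zeros(L if seq.circular else len(means) + window - 1, dtype=bool)
        for s0 in qualifying:
            if seq.circular:
                idx = (np.arange(s0, s0 + window)) % L
                cov[idx] = True
            else:
                cov[s0 : s0 + window] = True
        for a, b in _covered_runs(cov, seq.circular):
            hits.append(
                G4Hit(
                    start=a + 1,
                    end=b + 1,
                    strand=strand,
                    score=_interval_scores(scores, a, b),
                )
            )
    hits.sort(key=lambda h: (h.start, h.end, h.strand))
    return hits


def annotate_hits(hits: list[G4Hit], table: FeatureTable, L: int) -> HitSummary:
    """Assign each hit the class of the feature containing its midpoint and
    summarize. Non-coding means D_loop or other_noncoding (intergenic);
    rRNA/tRNA genes are counted in their own classes."""
    counts = {c: 0 for c in FEATURE_CLASSES}
    n_dloop = 0
    for h in hits:
        if not (1 <= h.start <= L and 1 <= h.end <= L):
            raise ValueError(f"hit {h.start}-{h.end} outside [1, {L}]")
        mid = h.midpoint(L)
        counts[table.class_of(mid)] += 1
        if table.in_dloop(mid):
            n_dloop += 1
    n = len(hits)
    n_noncoding = counts["D_loop"] + counts["other_noncoding"]
    return HitSummary(
        n_total=n,
        fraction_protein_coding=counts["protein_coding"] / n if n else 0.0,
        fraction_noncoding=n_noncoding / n if n else 0.0,
        fraction_of_noncoding_in_dloop=(n_dloop / n_noncoding) if n_noncoding else 0.0,
        n_in_dloop=n_dloop,
        by_class=counts,
    )


def circular_interval_length(start: int, end: int, L: int) -> int:
    """Length of a 1-based interval on an L-base circle.

    Non-wrapping intervals (start <= end) count end - start + 1 bases.
    Wrapping intervals (start > end) use the one-endpoint-exclusive
    convention (L - start) + end, counting the origin once — the convention
    under which the mitochondrial control-region amplicon 16,067 -> 644 on
    the 16,569-bp circle measures 1,146 bp.
    """
    for name, pos in (("start", start), ("end", end)):
        if not 1 <= pos <= L:
            raise ValueError(f"{name}={pos} outside [1, {L}]")
    if start <= end:
        return end - start + 1
    return (L - start) + end


def region_extract(seq: CircularSequence, start: int, end: int) -> str:
    """Bases from start to end inclusive (1-based), wrapping the origin when
    start > end on a circular sequence."""
    L = len(seq)
    for name, pos in (("start", start), ("end", end)):
        if not 1 <= pos <= L:
            raise ValueError(f"{name}={pos} outside [1, {L}]")
    if start <= end:
        return seq.bases[start - 1 : end]
    if not seq.circular:
        raise ValueError("wrap-around extraction requested on a linear sequence")
    return seq.bases[start - 1 :] + seq.bases[:end]
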