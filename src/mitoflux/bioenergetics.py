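"""Closed-form bioenergetics metrics.

Mito Stress Test parameters derived from oxygen-consumption-rate (OCR)
traces, and indirect-calorimetry respiratory exchange ratio (RER) and
energy expenditure (EE).

The Mito Stress Test perturbs respiration with sequential injections:
oligomycin (blocks ATP synthase), FCCP (uncouples, drives maximal
respiration) and rotenone + antimycin A (shuts down the electron transport
chain, leaving only non-mitochondrial oxygen consumption). The derived
parameters decompose basal respiration into ATP-linked respiration and
proton leak, and measure spare respiratory capacity (SRC) as maximal minus
basal respiration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PHASES",
    "OcrTrace",
    "MitoStressParams",
    "mito_stress_params",
    "rer",
    "energy_expenditure",
    "CalorimetryRecord",
    "calorimetry_record",
]

#: Injection phases in protocol order.
PHASES = ("baseline", "oligomycin", "FCCP", "rot_AA")

# EE regression constants (kcal per litre O2 as a linear function of RER).
EE_INTERCEPT = 3.185
EE_SLOPE = 1.232


@dataclass(frozen=True)
class OcrTrace:
    """An OCR time series partitioned into Mito Stress Test phases.

    ``timepoints`` are minutes, ``ocr`` the oxygen consumption rate in
    pmol O2/min (assumed already normalized, e.g. to total protein), and
    ``phase`` one label per timepoint, appearing in protocol order
    baseline -> oligomycin -> FCCP -> rot_AA with >=2 points per phase.
    """

    timepoints: tuple
    ocr: tuple
    phase: tuple

    def __post_init__(self):
        if not (len(self.timepoints) == len(self.ocr) == len(self.phase)):
            raise ValueError("timepoints, ocr and phase must have equal length")
        if list(self.timepoints) != sorted(self.timepoints):
            raise ValueError("timepoints must be non-decreasing")
        seen = []
        for p in self.phase:
            if p not in PHASES:
                raise ValueError(f"unknown phase label: {p!r}")
            if not seen or seen[-1] != p:
                seen.append(p)
        expected = [p for p in PHASES if p in set(self.phase)]
        if seen != expected or seen != list(PHASES)[: len(seen)]:
            raise ValueError(
                f"phases must appear contiguously in order {PHASES}, got {seen}"
            )
        for p in set(self.phase):
            if sum(q == p for q in self.phase) < 2:
                raise ValueError(f"phase {p!r} has <2 measurements")

    def phase_values(self, label: str) -> np.ndarray:
        vals = np.asarray(
            [o for o, p in zip(self.ocr, self.phase) if p == label], dtype=float
        )
        if vals.size == 0:
            raise ValueError(f"missing phase: {label!r}")
        return vals

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OcrTrace":
        """Build from a table with columns time, ocr, phase."""
        need = {"time", "ocr", "phase"}
        if not need.issubset(df.columns):
            raise ValueError(f"trace table needs columns {sorted(need)}")
        df = df.sort_values("time", kind="stable")
        return cls(
            tuple(float(t) for t in df["time"]),
            tuple(float(v) for v in df["ocr"]),
            tuple(str(p) for p in df["phase"]),
        )


@dataclass(frozen=True)
class MitoStressParams:
    """Derived Mito Stress Test parameters (same units as the input OCR)."""

    basal: float
    maximal: float
    src: float
    atp_linked: float
    proton_leak: float
    non_mito: float


def _plateau(values: np.ndarray, k: int = 3) -> float:
    # Seahorse-style plateau: mean of the last k points of a phase.
    return float(np.mean(values[-k:]))


def mito_stress_params(trace: OcrTrace, raw: bool = False) -> MitoStressParams:
    """Compute Mito Stress Test parameters from an OCR trace.

    basal = plateau of the baseline phase; maximal = max of the FCCP phase;
    src = maximal - basal; atp_linked = basal - oligomycin plateau;
    proton_leak = oligomycin plateau - non-mitochondrial OCR;
    non_mito = rotenone/antimycin-A plateau. Plateaus are the mean of the
    last 3 points of the phase (all points if fewer).

    By default basal, maximal and the oligomycin plateau are reported as
    mitochondrial OCR, i.e. with non_mito subtracted; ``raw=True`` skips
    the subtraction.
    """
    for p in PHASES:
        if p not in trace.phase:
            raise ValueError(f"missing phase: {p!r}")
    basal_raw = _plateau(trace.phase_values("baseline"))
    oligo_raw = _plateau(trace.phase_values("oligomycin"))
    maximal_raw = float(np.max(trace.phase_values("FCCP")))
    non_mito = _plateau(trace.phase_values("rot_AA"))

    shift = 0.0 if raw else non_mito
    basal = basal_raw - shift
    maximal = maximal_raw - shift
    oligo = oligo_raw - shift
    return MitoStressParams(
        basal=basal,
        maximal=maximal,
        src=maximal - basal,
        atp_linked=basal - oligo,
        proton_leak=oligo_raw - non_mito,
        non_mito=non_mito,
    )


def rer(vco2: float, vo2: float) -> float:
    """Respiratory exchange ratio VCO2/VO2 (vo2 must be positive)."""
    if vo2 <= 0:
        raise ValueError(f"vo2 must be > 0, got {vo2}")
    if vco2 < 0:
        raise ValueError(f"vco2 must be >= 0, got {vco2}")
    return vco2 / vo2


def energy_expenditure(rer_value: float, vo2: float) -> float:
    """Energy expenditure (3.185 + 1.232 * RER) * VO2."""
    if vo2 <= 0:
        raise ValueError(f"vo2 must be > 0, got {vo2}")
    return (EE_INTERCEPT + EE_SLOPE * rer_value) * vo2


@dataclass(frozen=True)
class CalorimetryRecord:
    """One indirect-calorimetry interval: gas volumes plus derived RER/EE."""

    vo2: float
    vco2: float
    rer: float
    ee: float


def calorimetry_record(vo2: float, vco2: float) -> CalorimetryRecord:
    r = rer(vco2, vo2)
    return CalorimetryRecord(vo2=vo2, vco2=vco2, rer=r, ee=energy_expenditure(r, vo2))
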