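"""Seeded synthetic inputs with the statistical structure the analyses assume.

Three generators, all driven by a single seed through independent child
generators (no global random state):

* grouped expression matrices — log-normal abundances on a module-structured
  equicorrelated Gaussian latent, with a block of "mtDNA-encoded" genes
  down-regulated by a known factor in the Treated group and a TreatedInactive
  group generated identically to Control (emulating an inactive analogue that
  modulates no genes);
* small feasible metabolic networks — a linear chain (optionally with a
  parallel branch) from nutrient uptake to a biomass objective, every internal
  reaction carrying a GPR and a subsystem label, with the analytically known
  LP optimum recorded;
* DNA sequences with planted G-quadruplex motifs — canonical four-tract
  G3+ N1-7 motifs on a background whose G/C runs never exceed two bases, on a
  linear or circular backbone (with an origin-straddling motif when circular).

Every generator returns its ground truth alongside the data so downstream
recovery can be measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .fba import MetabolicModel, Reaction
from .g4 import CircularSequence

__all__ = [
    "GROUP_LABELS",
    "SimulationConfig",
    "PlantedTruth",
    "PlacementError",
    "generate_expression",
    "generate_toy_model",
    "generate_sequence_with_g4",
]

#: Condition labels, mirroring control / active compound / inactive analogue.
GROUP_LABELS = ("Control", "Treated", "TreatedInactive")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic expression generator.

    ``module_sizes`` partitions the first ``sum(module_sizes)`` genes into
    correlated modules; remaining genes are independent background. The
    first ``mt_block_size`` genes form the mtDNA-encoded block (named
    ``MT-0001`` ...) whose Treated-group abundance is multiplied by
    ``mt_downregulation_factor``; by default the block coincides with the
    first module so it surfaces as one branch of the network.
    ``noise_sd`` is the standard deviation of log2 abundance.
    """

    seed: int = 0
    n_per_group: dict = field(
        default_factory=lambda: {lab: 6 for lab in GROUP_LABELS}
    )
    n_genes: int = 66
    n_modules: int = 11
    module_sizes: tuple = (6,) * 11
    within_module_correlation: float = 0.7
    mt_block_size: int = 6
    mt_downregulation_factor: float = 0.5
    noise_sd: float = 1.0

    def __post_init__(self):
        if set(self.n_per_group) - set(GROUP_LABELS):
            raise ValueError(
                f"n_per_group labels must be among {GROUP_LABELS}"
            )
        for lab, n in self.n_per_group.items():
            if n < 1:
                raise ValueError(f"n_per_group[{lab!r}] must be >= 1, got {n}")
        if self.n_genes < 1:
            raise ValueError(f"n_genes must be >= 1, got {self.n_genes}")
        if len(self.module_sizes) != self.n_modules:
            raise ValueError(
                f"module_sizes has {len(self.module_sizes)} entries for "
                f"n_modules={self.n_modules}"
            )
        if any(m < 1 for m in self.module_sizes):
            raise ValueError("module_sizes entries must be >= 1")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError(
                f"sum(module_sizes)={sum(self.module_sizes)} exceeds "
                f"n_genes={self.n_genes}"
            )
        if not 0.0 <= self.within_module_correlation < 1.0:
            raise ValueError(
                "within_module_correlation must lie in [0, 1), got "
                f"{self.within_module_correlation}"
            )
        if not 1 <= self.mt_block_size <= self.n_genes:
            raise ValueError(
                f"mt_block_size={self.mt_block_size} outside [1, {self.n_genes}]"
            )
        if not 0.0 < self.mt_downregulation_factor <= 1.0:
            raise ValueError(
                "mt_downregulation_factor must lie in (0, 1], got "
                f"{self.mt_downregulation_factor}"
            )
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")


@dataclass
class PlantedTruth:
    """Ground truth recorded by a generator (unused fields stay empty)."""

    module_membership: dict = field(default_factory=dict)  # gene -> module id
    mt_genes: set = field(default_factory=set)
    planted_g4_intervals: list = field(default_factory=list)  # (start, end, strand)
    toy_lp_optimum: float | None = None


class PlacementError(ValueError):
    """Planted motifs cannot be placed without overlap."""


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def _gene_names(config: SimulationConfig) -> list:
    names = []
    for i in range(config.n_genes):
        if i < config.mt_block_size:
            names.append(f"MT-{i + 1:04d}")
        else:
            names.append(f"G{i + 1:04d}")
    return names


def generate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Draw a grouped FPKM-like matrix with correlated gene modules.

    log2 abundance of gene g in sample j is
    mu_g + noise_sd * (sqrt(rho) Z_m(j) + sqrt(1-rho) eps_gj), so the
    population correlation of two genes in the same module equals
    ``within_module_correlation`` on the log scale; abundances are
    2 ** (log2 value), hence strictly positive and log-normal. In the
    Treated group the mt-block values are multiplied by
    ``mt_downregulation_factor``, scaling their expectation by exactly that
    factor. TreatedInactive is generated identically to Control.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config)
    rho = config.within_module_correlation

    membership: dict = {}
    start = 0
    for m, size in enumerate(config.module_sizes):
        for g in genes[start : start + size]:
            membership[g] = m
        start += size
    # background genes get their own singleton module ids
    next_id = config.n_modules
    for g in genes[start:]:
        membership[g] = next_id
        next_id += 1

    # log2 FPKM baselines spanning ~3.5 orders of magnitude, as real
    # transcriptomes do (FPKM ~1 up to a few thousand)
    mu = rng.uniform(0.0, 12.0, size=config.n_genes)

    columns, labels = [], []
    values = np.empty((config.n_genes, 0))
    for lab in GROUP_LABELS:
        n = config.n_per_group.get(lab, 0)
        if n == 0:
            continue
        z = rng.standard_normal((next_id, n))  # one latent per module
        eps = rng.standard_normal((config.n_genes, n))
        module_of = np.array([membership[g] for g in genes])
        latent = np.sqrt(rho) * z[module_of] + np.sqrt(1.0 - rho) * eps
        log2v = mu[:, None] + config.noise_sd * latent
        v = np.power(2.0, log2v)
        if lab == "Treated":
            v[: config.mt_block_size] *= config.mt_downregulation_factor
        values = np.hstack([values, v])
        columns += [f"{lab}_{i + 1:02d}" for i in range(n)]
        labels += [lab] * n

    matrix = pd.DataFrame(values, index=genes, columns=columns)
    groups = pd.Series(labels, index=columns, name="group")
    truth = PlantedTruth(
        module_membership=membership,
        mt_genes=set(genes[: config.mt_block_size]),
    )
    return ExpressionMatrix(matrix, groups), truth


# ---------------------------------------------------------------------------
# Metabolic toy models
# ---------------------------------------------------------------------------

def generate_toy_model(
    seed: int = 0,
    n_linear_chain: int = 3,
    with_branch: bool = False,
    uptake_bound: float = 1.0,
    n_background: int = 10,
) -> tuple[MetabolicModel, PlantedTruth]:
    """A feasible toy network with a known biomass optimum.

    Chain topology: uptake -> M1 -> ... -> Mn -> biomass, every internal
    step capacity 1, so the optimum equals ``uptake_bound`` capped at 1.
    With ``with_branch=True`` a second parallel chain (its own uptake)
    feeds the same terminal metabolite, doubling the optimum.

    GPR structure mirrors genome-scale proportions at desk scale: chain
    reactions (subsystem "OXPHOS") carry two-isozyme OR rules over the
    mtDNA-encoded genes (``MT-0001`` ...), branch reactions ("Glycolysis")
    two-isozyme rules over nuclear genes, and ``n_background`` independent
    transport units ("Transport") carry single nuclear-gene rules. The
    background keeps the max-min normalization anchored the way a large
    network does — the lowest-expressed reaction is almost never inside
    the pathway under study, so closing it does not silence that pathway.
    Gene names match :func:`generate_expression`, so its matrices plug in
    directly; the seed only shuffles which gene each reaction gets.
    """
    if n_linear_chain < 2:
        raise ValueError(f"n_linear_chain must be >= 2, got {n_linear_chain}")
    if n_background < 0:
        raise ValueError(f"n_background must be >= 0, got {n_background}")
    rng = np.random.default_rng(seed)
    n = n_linear_chain
    mets = [f"M{i + 1}" for i in range(n)]
    reactions: dict = {}
    reactions["EX_M1"] = Reaction(
        "EX_M1", {"M1": 1.0}, 0.0, uptake_bound, subsystem="Exchange"
    )
    mt_names = [f"MT-{i + 1:04d}" for i in rng.permutation(6)]
    for i in range(n - 1):
        pair = (mt_names[(2 * i) % 6], mt_names[(2 * i + 1) % 6])
        reactions[f"R{i + 1}"] = Reaction(
            f"R{i + 1}", {mets[i]: -1.0, mets[i + 1]: 1.0}, 0.0, 1.0,
            gpr=f"{pair[0]} or {pair[1]}", subsystem="OXPHOS",
        )
    chain_cap = min(uptake_bound, 1.0)
    optimum = chain_cap
    if with_branch:
        bmets = [f"N{i + 1}" for i in range(n - 1)]
        mets += bmets
        reactions["EX_N1"] = Reaction(
            "EX_N1", {"N1": 1.0}, 0.0, uptake_bound, subsystem="Exchange"
        )
        path = bmets + [mets[n - 1]]  # joins the terminal chain metabolite
        nuc = [f"G{i + 7:04d}" for i in rng.permutation(6)]
        for i in range(len(path) - 1):
            pair = (nuc[(2 * i) % 6], nuc[(2 * i + 1) % 6])
            reactions[f"B{i + 1}"] = Reaction(
                f"B{i + 1}", {path[i]: -1.0, path[i + 1]: 1.0}, 0.0, 1.0,
                gpr=f"{pair[0]} or {pair[1]}", subsystem="Glycolysis",
            )
        optimum += chain_cap
    # independent uptake -> sink transport units, one single-gene GPR each;
    # the pool grows with n_background so each unit has its own gene
    bg_genes = [f"G{i + 13:04d}" for i in rng.permutation(n_background)]
    for i, gene in enumerate(bg_genes):
        met = f"W{i + 1}"
        mets.append(met)
        reactions[f"EX_W{i + 1}"] = Reaction(
            f"EX_W{i + 1}", {met: 1.0}, 0.0, 1.0, subsystem="Exchange"
        )
        reactions[f"T{i + 1}"] = Reaction(
            f"T{i + 1}", {met: -1.0}, 0.0, 1.0, gpr=gene, subsystem="Transport"
        )
    reactions["biomass"] = Reaction(
        "biomass", {mets[n - 1]: -1.0}, 0.0, 1000.0, subsystem="Biomass"
    )
    model = MetabolicModel(
        metabolites=mets, reactions=reactions, objective_reaction="biomass"
    )
    return model, PlantedTruth(toy_lp_optimum=optimum)


# ---------------------------------------------------------------------------
# Sequences with planted G-quadruplex motifs
# ---------------------------------------------------------------------------

def _motif(rng: np.random.Generator) -> str:
    """Canonical four-tract quadruplex motif: G-tracts of 3-4 separated by
    1-3 A/T loop bases (A/T only, so the motif itself sets the G4 signal)."""
    parts = []
    for t in range(4):
        parts.append("G" * int(rng.integers(3, 5)))
        if t < 3:
            loop = rng.choice(list("AT"), size=int(rng.integers(1, 4)))
            parts.append("".join(loop))
    return "".join(parts)


def _background(rng: np.random.Generator, length: int) -> list:
    """i.i.d.-ish uniform background with G and C runs capped at 2."""
    out: list = []
    for _ in range(length):
        choices = "ACGT"
        if len(out) >= 2 and out[-1] == out[-2] and out[-1] in "GC":
            choices = choices.replace(out[-1], "")
        out.append(choices[rng.integers(0, len(choices))])
    return out


def generate_sequence_with_g4(
    seed: int = 0,
    length: int = 5000,
    circular: bool = False,
    n_planted: int = 3,
    min_gap: int = 60,
) -> tuple[CircularSequence, PlantedTruth]:
    """A random sequence with ``n_planted`` non-overlapping G4 motifs.

    Background G/C runs never exceed two bases, so default-parameter
    scanning reports no background hits; each planted interval contains a
    four-tract motif flanked by T. On a circular backbone with
    ``n_planted >= 2`` one motif straddles the origin. Motifs are kept at
    least ``min_gap`` bases apart so each yields its own merged hit.
    """
    if length < 100:
        raise ValueError(f"length must be >= 100, got {length}")
    if n_planted < 0:
        raise ValueError("n_planted must be >= 0")
    rng = np.random.default_rng(seed)
    bases = _background(rng, length)

    motifs = [("T" + _motif(rng) + "T") for _ in range(n_planted)]
    slot = max(len(m) for m in motifs) if motifs else 0
    if n_planted and n_planted * (slot + min_gap) > length:
        raise PlacementError(
            f"cannot place {n_planted} motifs of <= {slot} bases with gaps "
            f"of {min_gap} in a {length}-base sequence"
        )
    intervals = []
    if n_planted:
        stride = length // n_planted
        for k, m in enumerate(motifs):
            if circular and n_planted >= 2 and k == 0:
                offset = length - len(m) // 2  # straddle the origin
            else:
                jitter = int(rng.integers(0, max(1, stride - slot - min_gap)))
                offset = k * stride + (min_gap // 2) + jitter
            for i, ch in enumerate(m):
                bases[(offset + i) % length] = ch
            # truth excludes the T flanks: the motif proper
            s0 = (offset + 1) % length
            e0 = (offset + len(m) - 2) % length
            intervals.append((s0 + 1, e0 + 1, "+"))
    seq = CircularSequence(f"synth_{seed}", "".join(bases), circular)
    truth = PlantedTruth(planted_g4_intervals=sorted(intervals))
    return seq, truth
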