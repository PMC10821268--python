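"""Expression-constrained flux balance analysis (E-flux).

The pipeline: gene-protein-reaction (GPR) boolean rules are evaluated
against expression values with OR resolved as the sum and AND as the
minimum of its operands; reaction scores are max-min normalized to [0, 1];
normalized scores scale the default reaction bounds (a score of 0 closes a
reaction, 1 leaves it fully open); the resulting linear program maximizes
the biomass objective under steady-state mass balance; pathway flux
activities sum the optimal fluxes per subsystem, and treatment effects are
reported as treated-minus-control activity deltas.
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .expression import ExpressionMatrix

__all__ = [
    "Reaction",
    "MetabolicModel",
    "GprTree",
    "parse_gpr",
    "resolve_gpr",
    "reaction_scores",
    "normalize_scores",
    "apply_eflux_bounds",
    "FluxSolution",
    "run_fba",
    "pathway_flux_activity",
    "delta_flux_activity",
    "PathwayActivityTable",
    "condition_pipeline",
]

ABSENT = None  # score of a reaction with no resolvable GPR


@dataclass
class Reaction:
    id: str
    stoichiometry: dict          # metabolite id -> coefficient (<0 consumed)
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    reversible: bool = False
    gpr: str = ""
    subsystem: str = ""

    def __post_init__(self):
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )


@dataclass
class MetabolicModel:
    """A stoichiometric network with GPRs, subsystems and a biomass objective.

    Exchange with the environment is modelled by reactions whose
    stoichiometry has a net total (boundary reactions); internal metabolites
    must all be declared in ``metabolites``.
    """

    metabolites: list
    reactions: dict = field(default_factory=dict)  # id -> Reaction
    objective_reaction: str = ""

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.objective_reaction not in self.reactions:
            raise ValueError(
                f"objective reaction {self.objective_reaction!r} not in model"
            )
        declared = set(self.metabolites)
        for rxn in self.reactions.values():
            unknown = set(rxn.stoichiometry) - declared
            if unknown:
                raise ValueError(
                    f"reaction {rxn.id!r} references undeclared metabolites "
                    f"{sorted(unknown)}"
                )
            if rxn.gpr:
                parse_gpr(rxn.gpr)  # fail fast on malformed rules

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)

    def stoichiometric_matrix(self) -> np.ndarray:
        met_idx = {m: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions.values()):
            for m, coef in rxn.stoichiometry.items():
                S[met_idx[m], j] = coef
        return S


# ---------------------------------------------------------------------------
# GPR parsing and resolution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GprTree:
    """Node of a parsed GPR: kind is GENE, AND or OR; AND/OR nodes hold >=2
    children, GENE leaves hold the gene id."""

    kind: str
    children: tuple = ()
    gene: str = ""

    def genes(self) -> set:
        if self.kind == "GENE":
            return {self.gene}
        out: set = set()
        for c in self.children:
            out |= c.genes()
        return out


class GprParseError(ValueError):
    pass


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(s: str):
    tokens = []
    for m in _TOKEN_RE.finditer(s):
        tok = m.group()
        low = tok.lower()
        if tok in "()":
            tokens.append((tok, m.start()))
        elif low in ("and", "or"):
            tokens.append((low, m.start()))
        else:
            tokens.append(("GENE", m.start(), tok))
    return tokens


@lru_cache(maxsize=16384)
def parse_gpr(gpr_string: str) -> GprTree:
    """Parse a boolean GPR string. ``and`` binds tighter than ``or``
    (case-insensitive); parentheses group; associativity is flattened into
    n-ary AND/OR nodes. Results are memoized (rules repeat across samples)."""
    tokens = _tokenize(gpr_string)
    if not tokens:
        raise GprParseError("empty GPR string")
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def fail(msg, at):
        raise GprParseError(f"{msg} at position {at}")

    def parse_or():
        nonlocal pos
        terms = [parse_and()]
        while peek() and peek()[0] == "or":
            pos += 1
            terms.append(parse_and())
        if len(terms) == 1:
            return terms[0]
        flat = []
        for t in terms:
            flat.extend(t.children if t.kind == "OR" else (t,))
        return GprTree("OR", tuple(flat))

    def parse_and():
        nonlocal pos
        factors = [parse_atom()]
        while peek() and peek()[0] == "and":
            pos += 1
            factors.append(parse_atom())
        if len(factors) == 1:
            return factors[0]
        flat = []
        for f in factors:
            flat.extend(f.children if f.kind == "AND" else (f,))
        return GprTree("AND", tuple(flat))

    def parse_atom():
        nonlocal pos
        tok = peek()
        if tok is None:
            fail("dangling operator", len(gpr_string))
        if tok[0] == "GENE":
            pos += 1
            return GprTree("GENE", gene=tok[2])
        if tok[0] == "(":
            open_at = tok[1]
            pos += 1
            node = parse_or()
            closing = peek()
            if closing is None or closing[0] != ")":
                fail("unbalanced parenthesis (missing ')')", open_at)
            pos += 1
            return node
        fail(f"unexpected token {tok[0]!r}", tok[1])

    tree = parse_or()
    if pos < len(tokens):
        fail(f"unexpected token {tokens[pos][0]!r}", tokens[pos][1])
    return tree


def resolve_gpr(tree: GprTree, gene_expression, missing: str = "partial"):
    """Evaluate a GPR against gene expression values.

    OR nodes sum their children; AND nodes take the minimum. Under the
    default ``missing='partial'`` policy an unresolvable gene acts as the
    identity of its parent operator (contributes 0 to an OR, is ignored in
    an AND's minimum provided a sibling resolves); a rule with no
    resolvable leaf returns ABSENT (None). ``missing='strict'`` raises on
    the first unknown gene instead.
    """
    if missing not in ("partial", "strict"):
        raise ValueError(f"unknown missing-gene policy {missing!r}")
    if tree.kind == "GENE":
        if tree.gene in gene_expression:
            v = float(gene_expression[tree.gene])
            if v < 0:
                raise ValueError(f"negative expression for gene {tree.gene!r}")
            return v
        if missing == "strict":
            raise KeyError(f"gene {tree.gene!r} missing from expression data")
        return ABSENT
    vals = [resolve_gpr(c, gene_expression, missing) for c in tree.children]
    resolved = [v for v in vals if v is not ABSENT]
    if not resolved:
        return ABSENT
    return sum(resolved) if tree.kind == "OR" else min(resolved)


def reaction_scores(
    model: MetabolicModel, gene_expression, missing: str = "partial"
) -> dict:
    """Raw (pre-normalization) GPR score per reaction; reactions with an
    empty or unresolvable GPR get ABSENT."""
    out = {}
    for rid, rxn in model.reactions.items():
        if not rxn.gpr:
            out[rid] = ABSENT
            continue
        out[rid] = resolve_gpr(parse_gpr(rxn.gpr), gene_expression, missing)
    return out


def normalize_scores(scores: dict) -> dict:
    """Max-min normalize resolvable scores onto [0, 1]; ABSENT entries pass
    through. When all resolvable scores are equal every score maps to 1
    (uniform expression must not close the network)."""
    vals = [v for v in scores.values() if v is not ABSENT]
    if not vals:
        raise ValueError("no resolvable reaction scores to normalize")
    lo, hi = min(vals), max(vals)
    if hi == lo:
        return {k: (ABSENT if v is ABSENT else 1.0) for k, v in scores.items()}
    return {
        k: (ABSENT if v is ABSENT else (v - lo) / (hi - lo))
        for k, v in scores.items()
    }


def apply_eflux_bounds(model: MetabolicModel, normalized: dict) -> MetabolicModel:
    """Return a bounded copy: a reaction with score s gets upper bound
    s * default_ub, and, if reversible, lower bound -s * |default_lb|.
    ABSENT scores leave default bounds untouched."""
    bounded = model.copy()
    for rid, s in normalized.items():
        if s is ABSENT or rid not in bounded.reactions:
            continue
        if not 0.0 <= s <= 1.0 + 1e-12:
            raise ValueError(f"normalized score for {rid!r} outside [0,1]: {s}")
        rxn = bounded.reactions[rid]
        rxn.upper_bound = s * rxn.upper_bound
        if rxn.reversible:
            rxn.lower_bound = -s * abs(rxn.lower_bound)
    return bounded


# ---------------------------------------------------------------------------
# Linear programming
# ---------------------------------------------------------------------------

@dataclass
class FluxSolution:
    flux: dict                    # reaction id -> flux
    objective_value: float
    status: str                   # optimal | infeasible | unbounded

    def flux_vector(self, model: MetabolicModel) -> np.ndarray:
        return np.array([self.flux[r] for r in model.reactions])


_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def run_fba(model: MetabolicModel, parsimonious: bool = False) -> FluxSolution:
    """Maximize flux through the objective reaction subject to S v = 0 and
    the reaction bounds.

    With ``parsimonious=True`` a second LP minimizes total absolute flux at
    the fixed optimal objective, selecting a unique, minimal-flux optimum
    (useful because FBA optima are generally non-unique).
    """
    rids = list(model.reactions)
    n = len(rids)
    S = model.stoichiometric_matrix()
    c = np.zeros(n)
    c[rids.index(model.objective_reaction)] = -1.0  # linprog minimizes
    bounds = [
        (model.reactions[r].lower_bound, model.reactions[r].upper_bound)
        for r in rids
    ]
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds,
                  method="highs")
    status = _STATUS.get(res.status)
    if status is None:
        raise RuntimeError(f"LP solver failure: {res.message}")
    if status != "optimal":
        return FluxSolution(flux={r: np.nan for r in rids},
                            objective_value=np.nan, status=status)
    obj = -res.fun
    v = res.x
    if parsimonious:
        # min sum t, t >= v, t >= -v, objective pinned at its optimum
        c2 = np.concatenate([np.zeros(n), np.ones(n)])
        A_eq = np.hstack([S, np.zeros_like(S)])
        obj_row = np.zeros(2 * n)
        obj_row[rids.index(model.objective_reaction)] = 1.0
        A_eq = np.vstack([A_eq, obj_row])
        b_eq = np.concatenate([np.zeros(S.shape[0]), [obj]])
        A_ub = np.vstack([
            np.hstack([np.eye(n), -np.eye(n)]),    # v - t <= 0
            np.hstack([-np.eye(n), -np.eye(n)]),   # -v - t <= 0
        ])
        b_ub = np.zeros(2 * n)
        bounds2 = bounds + [(0, None)] * n
        res2 = linprog(c2, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                       bounds=bounds2, method="highs")
        if res2.status == 0:
            v = res2.x[:n]
    return FluxSolution(flux=dict(zip(rids, v)), objective_value=float(obj),
                        status="optimal")


def pathway_flux_activity(
    solution: FluxSolution, model: MetabolicModel, signed: bool = False
) -> dict:
    """Flux activity per pathway (subsystem): the sum of |v| over the
    pathway's reactions (``signed=True`` sums raw fluxes instead, where
    opposite-direction reversible fluxes can cancel)."""
    if solution.status != "optimal":
        raise ValueError(f"cannot summarize a {solution.status} solution")
    out: dict = {}
    for rid, rxn in model.reactions.items():
        key = rxn.subsystem or ""
        v = solution.flux[rid]
        out[key] = out.get(key, 0.0) + (v if signed else abs(v))
    return out


def delta_flux_activity(treated: dict, control: dict) -> dict:
    """treated - control per pathway; negative deltas mean the pathway's
    activity decreased under treatment."""
    missing = sorted(set(treated) ^ set(control))
    if missing:
        raise ValueError(f"pathway keys differ between conditions: {missing}")
    return {k: treated[k] - control[k] for k in treated}


# ---------------------------------------------------------------------------
# Condition pipeline
# ---------------------------------------------------------------------------

@dataclass
class PathwayActivityTable:
    """Mean pathway flux activity per condition plus treated-minus-control
    deltas (one column per non-control condition)."""

    activity: pd.DataFrame        # pathway x condition
    deltas: pd.DataFrame          # pathway x treated condition
    control: str
    per_sample: pd.DataFrame = None   # pathway x sample (when per-sample mode)


def condition_pipeline(
    model: MetabolicModel,
    expr: ExpressionMatrix,
    control: str = "Control",
    per_sample: bool = True,
    signed: bool = False,
    parsimonious: bool = False,
    missing: str = "partial",
) -> PathwayActivityTable:
    """Full E-flux procedure per sample (or per condition-mean expression):
    GPR resolution -> max-min normalization -> bound injection -> FBA ->
    pathway activities; condition activity is the mean over its samples,
    and deltas compare every treated condition against the control."""
    labels = expr.condition_labels()
    if control not in labels:
        raise ValueError(f"control condition {control!r} not among {labels}")
    for lab in labels:
        if not expr.samples_in(lab):
            raise ValueError(f"condition {lab!r} has no samples")

    def activities_for(values: pd.Series) -> dict:
        scores = reaction_scores(model, values, missing)
        normalized = normalize_scores(scores)
        bounded = apply_eflux_bounds(model, normalized)
        sol = run_fba(bounded, parsimonious=parsimonious)
        if sol.status != "optimal":
            raise RuntimeError(f"FBA {sol.status} for a sample/condition")
        return pathway_flux_activity(sol, model, signed=signed)

    if per_sample:
        per_sample_acts = {
            s: activities_for(expr.values[s]) for s in expr.sample_ids
        }
        per_sample_df = pd.DataFrame(per_sample_acts)
        cond_df = pd.DataFrame({
            lab: per_sample_df[expr.samples_in(lab)].mean(axis=1)
            for lab in labels
        })
    else:
        per_sample_df = None
        cond_df = pd.DataFrame({
            lab: activities_for(expr.values[expr.samples_in(lab)].mean(axis=1))
            for lab in labels
        })

    deltas = pd.DataFrame({
        lab: cond_df[lab] - cond_df[control]
        for lab in labels if lab != control
    })
    return PathwayActivityTable(activity=cond_df, deltas=deltas,
                                control=control, per_sample=per_sample_df)
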