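"""Readers and writers for the pipeline's on-disk formats.

Tabular data is TSV (UTF-8, '.' decimal); sequences are FASTA with an
optional ``circular=true`` token in the description line; metabolic models
use a native JSON schema (with optional SBML import when cobra is
available); gene sets are GMT; graphs export to GraphML. Coordinates are
1-based inclusive internally; BED export converts to 0-based half-open.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .expression import ExpressionMatrix
from .fba import MetabolicModel, Reaction
from .g4 import CircularSequence, FeatureTable, G4Hit

__all__ = [
    "read_expression", "write_expression",
    "read_fasta", "write_fasta",
    "read_model", "write_model",
    "read_gmt", "read_feature_table", "load_mtdna_features",
    "write_hits", "write_graphml",
]


def _header_comment(**params) -> str:
    kv = " ".join(f"{k}={v}" for k, v in params.items())
    return f"# mitoflux {__version__} {kv}".rstrip() + "\n"


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def read_expression(path, groups_path) -> ExpressionMatrix:
    """Expression TSV (first column gene ids, header sample ids) plus a
    sample-to-group sidecar TSV with columns sample, group."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if not df.index.is_unique:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene id in {path}: {dup!r}")
    bad = df.columns[~df.dtypes.map(pd.api.types.is_numeric_dtype)]
    if len(bad):
        col = bad[0]
        row = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
        raise ValueError(f"non-numeric cell in {path} at row {row!r}, column {col!r}")
    gdf = pd.read_csv(groups_path, sep="\t", comment="#")
    if not {"sample", "group"}.issubset(gdf.columns):
        raise ValueError(f"{groups_path} needs columns sample, group")
    groups = pd.Series(gdf["group"].values, index=gdf["sample"].values, name="group")
    return ExpressionMatrix(df, groups)


def write_expression(expr: ExpressionMatrix, path, groups_path, **params) -> None:
    path, groups_path = Path(path), Path(groups_path)
    with open(path, "w") as fh:
        fh.write(_header_comment(format="expression", **params))
        expr.values.to_csv(fh, sep="\t", index_label="gene")
    with open(groups_path, "w") as fh:
        fh.write(_header_comment(format="groups", **params))
        fh.write("sample\tgroup\n")
        for s, g in expr.groups.items():
            fh.write(f"{s}\t{g}\n")


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

def read_fasta(path, circular: bool = False) -> list[CircularSequence]:
    """All records of a FASTA file, uppercased; a record is circular when
    the flag is set or its description carries a ``circular=true`` token."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    out = []
    for rec in records:
        circ = circular or "circular=true" in rec.description.lower()
        out.append(CircularSequence(rec.id, str(rec.seq).upper(), circ))
    return out


def write_fasta(seqs: list[CircularSequence], path) -> None:
    records = [
        SeqRecord(
            Seq(s.bases), id=s.id,
            description="circular=true" if s.circular else "",
        )
        for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Metabolic models
# ---------------------------------------------------------------------------

def read_model(path) -> MetabolicModel:
    """Native JSON model (or SBML when the extension is .xml/.sbml and
    cobra is installed). GPR strings are parsed eagerly so malformed rules
    fail at load time, naming the reaction."""
    path = Path(path)
    if path.suffix.lower() in (".xml", ".sbml"):
        return _read_sbml(path)
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("metabolites", "reactions", "objective"):
        if key not in doc:
            raise ValueError(f"model JSON missing /{key}")
    reactions = {}
    for rid, spec in doc["reactions"].items():
        try:
            reactions[rid] = Reaction(
                rid,
                {m: float(c) for m, c in spec["stoichiometry"].items()},
                float(spec.get("lower_bound", 0.0)),
                float(spec.get("upper_bound", 1000.0)),
                bool(spec.get("reversible", False)),
                str(spec.get("gpr", "")),
                str(spec.get("subsystem", "")),
            )
        except KeyError as exc:
            raise ValueError(f"/reactions/{rid}: missing {exc}") from exc
    try:
        return MetabolicModel(
            metabolites=list(doc["metabolites"]),
            reactions=reactions,
            objective_reaction=doc["objective"],
        )
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_model(model: MetabolicModel, path) -> None:
    doc = {
        "metabolites": list(model.metabolites),
        "objective": model.objective_reaction,
        "reactions": {
            r.id: {
                "stoichiometry": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "reversible": r.reversible,
                "gpr": r.gpr,
                "subsystem": r.subsystem,
            }
            for r in model.reactions.values()
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _read_sbml(path) -> MetabolicModel:
    try:
        import cobra
    except ImportError as exc:  # pragma: no cover
        raise ImportError("SBML import requires the cobra package") from exc
    cm = cobra.io.read_sbml_model(str(path))
    reactions = {}
    for rxn in cm.reactions:
        reactions[rxn.id] = Reaction(
            rxn.id,
            {m.id: float(c) for m, c in rxn.metabolites.items()},
            float(rxn.lower_bound),
            float(rxn.upper_bound),
            rxn.lower_bound < 0,
            rxn.gene_reaction_rule or "",
            rxn.subsystem or "",
        )
    objective = None
    for rxn in cm.reactions:
        if rxn.objective_coefficient:
            objective = rxn.id
            break
    if objective is None:
        raise ValueError(f"{path}: no objective reaction in SBML model")
    return MetabolicModel(
        metabolites=[m.id for m in cm.metabolites],
        reactions=reactions,
        objective_reaction=objective,
    )


# ---------------------------------------------------------------------------
# Gene sets, feature tables, hits, graphs
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict:
    """GMT gene-set collection: name <tab> description <tab> genes..."""
    sets: dict = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs >=3 fields")
            sets[parts[0]] = set(g for g in parts[2:] if g)
    if not sets:
        raise ValueError(f"no gene sets in {path}")
    return sets


def read_feature_table(path) -> FeatureTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    return FeatureTable.from_frame(df)


def load_mtdna_features() -> FeatureTable:
    """The bundled human mitochondrial (rCRS) gene coordinate table."""
    ref = resources.files("mitoflux.data") / "mtdna_features.tsv"
    with resources.as_file(ref) as p:
        return read_feature_table(p)


def write_hits(hits: list[G4Hit], path, L: int, fmt: str = "tsv", **params) -> None:
    """Hits as TSV (1-based inclusive) or BED (0-based half-open; a hit
    wrapping the origin becomes two BED lines)."""
    path = Path(path)
    with open(path, "w") as fh:
        if fmt == "tsv":
            fh.write(_header_comment(format="g4hits", **params))
            fh.write("start\tend\tstrand\tscore\tlength\n")
            for h in hits:
                fh.write(f"{h.start}\t{h.end}\t{h.strand}\t{h.score:.4f}\t{h.length(L)}\n")
        elif fmt == "bed":
            for i, h in enumerate(hits):
                name = f"G4_{i + 1}"
                score = min(1000, int(round(abs(h.score) * 250)))
                if h.start <= h.end:
                    fh.write(f"seq\t{h.start - 1}\t{h.end}\t{name}\t{score}\t{h.strand}\n")
                else:  # wrap: emit the two arcs
                    fh.write(f"seq\t{h.start - 1}\t{L}\t{name}a\t{score}\t{h.strand}\n")
                    fh.write(f"seq\t0\t{h.end}\t{name}b\t{score}\t{h.strand}\n")
        else:
            raise ValueError(f"unknown hits format {fmt!r}")


def write_graphml(graph, path) -> None:
    nx.write_graphml(graph.graph, str(path))
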