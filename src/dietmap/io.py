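"""Readers and writers for the pipeline's plain-text interchange formats.

Formats
-------
* expression matrix: TSV, gene id column first, samples as columns
* sample metadata: TSV with columns sample_id, tissue, group, replicate
* gene annotation: TSV with columns gene_id, chromosome, position_bp
* gene sets: GMT (name, description, tab-separated member ids)
* metabolic model: TSV triples ``reaction_id  gene_id  metabolite_id``,
  one association per row, exactly one of gene/metabolite empty
* regulator targets: TSV long format ``regulator_id  gene_id  type``
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .networks import FeatureNetwork
from .study import ExpressionStudy

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression_study", "write_expression_study",
    "read_gmt", "write_gmt",
    "read_model_triples", "write_model_triples",
    "read_regulator_targets", "write_regulator_targets",
]


# -- expression study ---------------------------------------------------------

def read_expression_study(expression_path, metadata_path, annotation_path=None) -> ExpressionStudy:
    expr = pd.read_csv(expression_path, sep="\t", index_col=0)
    expr.index = expr.index.astype(str)
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str}).set_index("sample_id")
    genes = None
    if annotation_path is not None:
        genes = pd.read_csv(
            annotation_path, sep="\t", dtype={"gene_id": str, "chromosome": str}
        ).set_index("gene_id")
    return ExpressionStudy(expr, meta, genes)


def write_expression_study(study: ExpressionStudy, expression_path, metadata_path,
                           annotation_path=None, float_format: str = "%.6f") -> None:
    study.expression.to_csv(expression_path, sep="\t", index_label="gene_id",
                            float_format=float_format)
    study.samples.to_csv(metadata_path, sep="\t", index_label="sample_id")
    if annotation_path is not None:
        if study.genes is None:
            raise ValueError("study has no gene annotation to write")
        study.genes.to_csv(annotation_path, sep="\t", index_label="gene_id")


# -- GMT gene sets ------------------------------------------------------------

def read_gmt(path, kind: str = "gene_set_collection", provenance: str = "") -> FeatureNetwork:
    """Parse a GMT file into a :class:`FeatureNetwork`.

    Each line: set name, description, then one gene id per tab field.
    Duplicate members within one set and duplicate set names are rejected.
    """
    features: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, _description, *members = fields
            members = [m for m in members if m]
            if name in features:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            if len(set(members)) != len(members):
                raise ValueError(f"{path}:{lineno}: duplicate member inside set {name!r}")
            if not members:
                raise ValueError(f"{path}:{lineno}: set {name!r} has no members")
            features[name] = frozenset(members)
    return FeatureNetwork(features, kind=kind, provenance=provenance or str(path))


def write_gmt(network: FeatureNetwork, path, descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name in sorted(network.features):
            members = sorted(network.features[name])
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


# -- metabolic model triples --------------------------------------------------

TRIPLE_COLUMNS = ["reaction_id", "gene_id", "metabolite_id"]


def read_model_triples(path) -> pd.DataFrame:
    """Read gene-reaction-metabolite association triples.

    Each row carries exactly one association: either (reaction, gene) with
    an empty metabolite cell, or (reaction, metabolite) with an empty gene
    cell.  Rows violating that are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != TRIPLE_COLUMNS:
        raise ValueError(f"model triples must have columns {TRIPLE_COLUMNS}, got {list(df.columns)}")
    has_gene = df["gene_id"] != ""
    has_met = df["metabolite_id"] != ""
    bad = df.index[(has_gene == has_met) | (df["reaction_id"] == "")]
    if len(bad):
        raise ValueError(
            f"{path}: {len(bad)} malformed triple rows (first at data row {bad[0] + 1}); "
            "each row needs a reaction id and exactly one of gene_id/metabolite_id"
        )
    return df


def write_model_triples(df: pd.DataFrame, path) -> None:
    df.loc[:, TRIPLE_COLUMNS].to_csv(path, sep="\t", index=False)


# -- regulator targets --------------------------------------------------------

REGULATOR_TYPES = ("TF", "miRNA")


def read_regulator_targets(path) -> pd.DataFrame:
    """Read the regulator->target long table (columns regulator_id, gene_id, type)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["regulator_id", "gene_id", "type"]
    if list(df.columns) != expected:
        raise ValueError(f"regulator table must have columns {expected}, got {list(df.columns)}")
    bad_types = set(df["type"]) - set(REGULATOR_TYPES)
    if bad_types:
        raise ValueError(f"unknown regulator types {sorted(bad_types)}; expected {REGULATOR_TYPES}")
    return df


def write_regulator_targets(df: pd.DataFrame, path) -> None:
    df.loc[:, ["regulator_id", "gene_id", "type"]].to_csv(path, sep="\t", index=False)


def targets_by_regulator(df: pd.DataFrame, universe=None) -> dict[str, frozenset[str]]:
    """Collapse the long table to regulator -> target gene set.

    If ``universe`` is given, targets are restricted to it; regulators left
    with no resolvable target are dropped with a log entry.
    """
    mapping = {reg: frozenset(sub["gene_id"]) for reg, sub in df.groupby("regulator_id")}
    if universe is not None:
        universe = frozenset(universe)
        resolved = {}
        dropped = 0
        for reg in sorted(mapping):
            kept = mapping[reg] & universe
            if kept:
                resolved[reg] = kept
            else:
                dropped += 1
        if dropped:
            logger.info("targets_by_regulator: dropped %d regulators with no resolvable target", dropped)
        mapping = resolved
    return mapping
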