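"""Differential-expression statistics for the multi-tissue two-diet design.

Covers the primary statistical pass over the normalized log2 matrix:

* quantile normalization across samples;
* an SVD overview of the centered matrix (the sanity check that tissue
  identity, not diet, dominates the leading components);
* per-tissue two-sample Student t-tests of diet within each tissue,
  with the log2 fold-change reported as second group minus first group
  (herring minus beef in the default design);
* per-gene balanced two-way ANOVA (tissue, diet, interaction);
* Benjamini-Hochberg FDR adjustment ("Q-values");
* a genome-ordered, BED-like export of -log10 Q per tissue for circular
  chromosome plots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .study import CHROMOSOME_ORDER, ExpressionStudy

logger = logging.getLogger(__name__)

__all__ = [
    "quantile_normalize", "svd_overview", "SvdSummary",
    "per_tissue_ttest", "two_way_anova", "adjust_q", "estimate_pi0",
    "significant_genes", "circular_map_export", "sample_distances",
]

#: lower clamp applied to p-values before log or inverse-normal transforms
P_EPS = 1e-16


# -- normalization ------------------------------------------------------------

def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns to a common distribution.

    Every column's sorted values are replaced by the row-wise mean of all
    column-sorted values; ties within a column receive the mean of the
    reference values across their rank span (so tied inputs stay tied).
    Idempotent: a normalized matrix maps to itself.
    """
    values = matrix.to_numpy(dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("quantile normalization needs at least two sample columns")
    if not np.isfinite(values).all():
        raise ValueError("matrix contains non-finite values")
    n = values.shape[0]
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(values.shape[1]):
        ranks = stats.rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


# -- SVD overview -------------------------------------------------------------

@dataclass
class SvdSummary:
    """Decomposition of the gene-centered matrix.

    ``sample_loadings`` holds the sample coordinates on each component
    (right singular vectors scaled by the singular values), which is what
    separation plots use.
    """

    singular_values: np.ndarray
    variance_fraction: np.ndarray
    sample_loadings: pd.DataFrame  # samples x components

    def to_frame(self) -> pd.DataFrame:
        comps = [f"PC{i + 1}" for i in range(len(self.singular_values))]
        return pd.DataFrame(
            {"singular_value": self.singular_values, "variance_fraction": self.variance_fraction},
            index=pd.Index(comps, name="component"),
        )


def svd_overview(study: ExpressionStudy) -> SvdSummary:
    """SVD of the row-centered expression matrix.

    Genes are centered (row mean subtracted), not scaled, so component
    variance fractions read as a decomposition of expression variance.
    An all-constant matrix yields zero singular values (no exception).
    """
    x = study.expression.to_numpy(dtype=float)
    centered = x - x.mean(axis=1, keepdims=True)
    _u, s, vt = np.linalg.svd(centered, full_matrices=False)
    total = float(np.sum(s**2))
    frac = s**2 / total if total > 0 else np.zeros_like(s)
    loadings = pd.DataFrame(
        (vt * s[:, None]).T,
        index=study.expression.columns,
        columns=[f"PC{i + 1}" for i in range(len(s))],
    )
    return SvdSummary(s, frac, loadings)


# -- per-gene tests -----------------------------------------------------------

def per_tissue_ttest(study: ExpressionStudy, tissue: str, welch: bool = False,
                     q_method: str = "bh") -> pd.DataFrame:
    """Two-sample t-test of diet group within one tissue, per gene.

    Classical equal-variance Student t by default (df = n1 + n2 - 2);
    Welch's unequal-variance variant behind ``welch=True``.  The log2
    fold-change is mean(second group) - mean(first group).  Degenerate
    genes with zero pooled variance get p = 1 when the means agree and
    p clamped to ``P_EPS`` when they differ.
    """
    g1, g2 = study.groups[0], study.groups[1]
    cols1 = study.samples_where(tissue=tissue, group=g1)
    cols2 = study.samples_where(tissue=tissue, group=g2)
    n1, n2 = len(cols1), len(cols2)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"tissue {tissue!r} needs >=2 replicates per group, got {n1} vs {n2}")
    x1 = study.expression[cols1].to_numpy(dtype=float)
    x2 = study.expression[cols2].to_numpy(dtype=float)
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1, v2 = x1.var(axis=1, ddof=1), x2.var(axis=1, ddof=1)
    log2fc = m2 - m1

    if welch:
        se2 = v1 / n1 + v2 / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            t = log2fc / np.sqrt(se2)
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = log2fc / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = np.full_like(t, float(n1 + n2 - 2))

    degenerate = ~np.isfinite(t)
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate, np.where(log2fc == 0.0, 0.0, np.sign(log2fc) * np.inf), t)
    p = np.where(np.isfinite(t), 2.0 * stats.t.sf(np.abs(np.where(np.isfinite(t), t, 0.0)), df), P_EPS)
    p = np.where(degenerate & (log2fc == 0.0), 1.0, p)
    p = np.clip(p, P_EPS, 1.0)

    return pd.DataFrame(
        {"log2fc": log2fc, "t_stat": t, "p_value": p, "q_value": adjust_q(p, q_method)},
        index=study.gene_ids.rename("gene_id"),
    )


def two_way_anova(study: ExpressionStudy, q_method: str = "bh") -> pd.DataFrame:
    """Per-gene fixed-effects two-way ANOVA with interaction.

    Requires a balanced design (equal replicates in every tissue x group
    cell), under which type I/II/III sums of squares coincide and the
    closed-form cell-mean decomposition below is exact.
    """
    tissues, groups = study.tissues, study.groups
    meta = study.samples
    cells = {}
    n_rep = None
    for t in tissues:
        for g in groups:
            cols = study.samples_where(tissue=t, group=g)
            if n_rep is None:
                n_rep = len(cols)
            elif len(cols) != n_rep:
                raise ValueError("unbalanced design: unequal replicates per tissue x group cell")
            cells[(t, g)] = study.expression[cols].to_numpy(dtype=float)
    if n_rep is None or n_rep < 2:
        raise ValueError("two-way ANOVA needs >=2 replicates per cell")

    a, b, n = len(tissues), len(groups), n_rep
    n_genes = study.expression.shape[0]
    cell_means = np.empty((n_genes, a, b))
    ss_err = np.zeros(n_genes)
    for i, t in enumerate(tissues):
        for j, g in enumerate(groups):
            x = cells[(t, g)]
            cell_means[:, i, j] = x.mean(axis=1)
            ss_err += ((x - cell_means[:, i, j][:, None]) ** 2).sum(axis=1)

    grand = cell_means.mean(axis=(1, 2))
    tissue_means = cell_means.mean(axis=2)
    group_means = cell_means.mean(axis=1)
    ss_tissue = n * b * ((tissue_means - grand[:, None]) ** 2).sum(axis=1)
    ss_diet = n * a * ((group_means - grand[:, None]) ** 2).sum(axis=1)
    interaction = (
        cell_means - tissue_means[:, :, None] - group_means[:, None, :] + grand[:, None, None]
    )
    ss_int = n * (interaction**2).sum(axis=(1, 2))

    df_tissue, df_diet = a - 1, b - 1
    df_int = (a - 1) * (b - 1)
    df_err = a * b * (n - 1)
    ms_err = ss_err / df_err

    out = {"gene_id": study.gene_ids}
    for label, ss, df in (
        ("tissue", ss_tissue, df_tissue),
        ("diet", ss_diet, df_diet),
        ("interaction", ss_int, df_int),
    ):
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss / df) / ms_err
        f = np.where(np.isfinite(f), f, np.where(ss > 0, np.inf, 0.0))
        p = np.where(np.isfinite(f), stats.f.sf(np.where(np.isfinite(f), f, 0.0), df, df_err), P_EPS)
        p = np.clip(p, P_EPS, 1.0)
        out[f"F_{label}"] = f
        out[f"p_{label}"] = p
        out[f"q_{label}"] = adjust_q(p, q_method)
    return pd.DataFrame(out).set_index("gene_id")


# -- multiple testing ---------------------------------------------------------

def adjust_q(p_values, method: str = "bh") -> np.ndarray:
    """FDR adjustment ("Q-values").

    ``method="bh"`` (default): Benjamini-Hochberg step-up,
    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1 and order-preserving on
    the sorted p-values.  ``method="storey"``: the same step-up scaled by
    an estimate of the true-null fraction pi0 (see :func:`estimate_pi0`),
    which is less conservative when many genes respond.  NaN rejected.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d p-value vector")
    if np.isnan(p).any():
        raise ValueError("NaN p-values not allowed")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    if method == "bh":
        return q
    if method == "storey":
        return np.minimum(estimate_pi0(p) * q, 1.0)
    raise ValueError("method must be 'bh' or 'storey'")


def estimate_pi0(p_values, lambda_: float = 0.5) -> float:
    """Fraction of true nulls estimated from the flat tail of the p spectrum.

    pi0 = #{p > lambda} / (m * (1 - lambda)), clipped to (0, 1]; under a
    complete null this is ~1 and the Storey adjustment reduces to BH.
    """
    p = np.asarray(p_values, dtype=float)
    if not 0 < lambda_ < 1:
        raise ValueError("lambda_ must lie in (0, 1)")
    pi0 = float((p > lambda_).mean() / (1.0 - lambda_))
    return min(max(pi0, 1.0 / max(p.size, 1)), 1.0)


def significant_genes(stat_table: pd.DataFrame, q_cut: float = 0.05,
                      q_col: str = "q_value") -> set[str]:
    """Genes with q strictly below the cut-off."""
    return set(stat_table.index[stat_table[q_col] < q_cut])


def sample_distances(study: ExpressionStudy, gene_subset=None,
                     metric: str = "euclidean") -> pd.DataFrame:
    """Sample x sample distance matrix, the plot-ready input for sample
    clustering heatmaps.

    ``metric`` is ``"euclidean"`` or ``"correlation"`` (1 - Pearson over
    genes); optionally restricted to a gene subset (e.g. the significant
    genes).
    """
    expr = study.expression if gene_subset is None else study.expression.loc[list(gene_subset)]
    x = expr.to_numpy(dtype=float).T  # samples x genes
    if metric == "euclidean":
        sq = (x**2).sum(axis=1)
        d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
        d = np.sqrt(np.clip(d2, 0.0, None))
    elif metric == "correlation":
        d = 1.0 - np.corrcoef(x)
    else:
        raise ValueError("metric must be 'euclidean' or 'correlation'")
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=expr.columns, columns=expr.columns)


# -- genome-ordered export ----------------------------------------------------

def circular_map_export(stat_tables: dict[str, pd.DataFrame],
                        annotation: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready table of -log10 Q per tissue in genome order.

    Rows are sorted by chromosome (autosomes 1..19 then X) and position;
    the output is BED-like (0-based ``start``, half-open interval of
    length 1).  Genes without annotation are dropped with a logged count.
    """
    if not stat_tables:
        raise ValueError("no stat tables given")
    gene_union = sorted(set().union(*(set(t.index) for t in stat_tables.values())))
    annotated = [g for g in gene_union if g in annotation.index]
    n_dropped = len(gene_union) - len(annotated)
    if n_dropped:
        logger.info("circular_map_export: dropped %d genes without annotation", n_dropped)

    chrom_rank = {c: i for i, c in enumerate(CHROMOSOME_ORDER)}
    rows = annotation.loc[annotated, ["chromosome", "position_bp"]].copy()
    unknown = set(rows["chromosome"]) - set(chrom_rank)
    if unknown:
        raise ValueError(f"unknown chromosomes in annotation: {sorted(unknown)}")
    rows["_rank"] = rows["chromosome"].map(chrom_rank)
    rows = rows.sort_values(["_rank", "position_bp"], kind="mergesort")

    out = pd.DataFrame({
        "chrom": rows["chromosome"].to_numpy(),
        "start": rows["position_bp"].to_numpy(dtype=int),
        "end": rows["position_bp"].to_numpy(dtype=int) + 1,
        "gene_id": rows.index.to_numpy(),
    })
    for tissue, table in stat_tables.items():
        q = table["q_value"].reindex(rows.index).to_numpy(dtype=float)
        out[f"neglog10q_{tissue}"] = -np.log10(np.clip(q, P_EPS, 1.0))
    return out.reset_index(drop=True)
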