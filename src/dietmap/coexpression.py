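"""Weighted co-expression network modules via topological overlap.

Builds the cross-tissue co-expression network on the diet-responsive gene
list (ANOVA diet-factor q below a cut), using soft-thresholded correlation
adjacency ``a_ij = |cor(x_i, x_j)|^beta``, the topological overlap matrix

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_u a_iu * a_uj,   k_i = sum_u a_iu,

and average-linkage hierarchical clustering of the dissimilarity
``1 - TOM`` with a static height cut to define modules.  Modules are then
tested for functional enrichment against a gene-set collection with the
one-sided Fisher exact test over the analyzed gene list as universe.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .differential import adjust_q
from .networks import FeatureNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "select_diet_genes", "adjacency", "tom", "detect_modules", "module_enrichment",
    "scale_free_beta",
]

UNASSIGNED = "unassigned"


def select_diet_genes(anova_table: pd.DataFrame, q_cut: float = 0.05) -> list[str]:
    """Genes whose ANOVA diet-factor q is strictly below ``q_cut`` (sorted by id)."""
    return sorted(anova_table.index[anova_table["q_diet"] < q_cut])


def adjacency(expr_subset: pd.DataFrame, beta: float = 6.0,
              cor_type: str = "pearson", signed: bool = False) -> pd.DataFrame:
    """Soft-thresholded correlation adjacency ``|cor|^beta`` (zero diagonal).

    Unsigned by default (absolute correlation); ``signed=True`` uses
    ``((1 + cor) / 2)^beta`` so anti-correlated genes get low adjacency.
    Zero-variance genes have undefined correlation and are dropped with a
    log entry.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    if expr_subset.shape[1] < 4:
        raise ValueError("need at least 4 samples for a meaningful correlation network")
    x = expr_subset.to_numpy(dtype=float)
    sd = x.std(axis=1)
    keep = sd > 0
    if (~keep).any():
        logger.info("adjacency: dropped %d zero-variance genes", int((~keep).sum()))
        x = x[keep]
    genes = expr_subset.index[keep]
    if cor_type == "pearson":
        cor = np.corrcoef(x)
    elif cor_type == "spearman":
        cor = stats.spearmanr(x, axis=1).statistic
        cor = np.atleast_2d(cor)
    else:
        raise ValueError("cor_type must be 'pearson' or 'spearman'")
    cor = np.clip(cor, -1.0, 1.0)
    a = ((1.0 + cor) / 2.0) ** beta if signed else np.abs(cor) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=genes, columns=genes)


def tom(adjacency_matrix: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of a symmetric [0,1] adjacency.

    The diagonal is defined as 1; an isolated pair (both connectivities
    zero and no direct edge) gets TOM = 0 by convention.
    """
    a = adjacency_matrix.to_numpy(dtype=float)
    if a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if (a < 0).any() or (a > 1).any():
        raise ValueError("adjacency values must lie in [0, 1]")
    if np.abs(np.diag(a)).max() > 1e-12:
        raise ValueError("adjacency diagonal must be zero for TOM computation")
    l = a @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (l + a) / denom
    t = np.where(denom == 0.0, 0.0, t)
    t = np.clip(t, 0.0, 1.0)
    np.fill_diagonal(t, 1.0)
    return pd.DataFrame(t, index=adjacency_matrix.index, columns=adjacency_matrix.columns)


def detect_modules(tom_matrix: pd.DataFrame, min_module_size: int = 10,
                   cut_height: float = 0.85) -> pd.DataFrame:
    """Average-linkage clustering of ``1 - TOM`` with a static height cut.

    Clusters smaller than ``min_module_size`` are relabeled
    ``"unassigned"``; surviving modules are named M1, M2, ... in order of
    decreasing size (ties broken by smallest member gene id).  The
    procedure is deterministic and invariant to gene ordering (up to
    exact dissimilarity ties).  All genes unassigned is a legal outcome.
    """
    genes = list(tom_matrix.index)
    d = 1.0 - tom_matrix.to_numpy(dtype=float)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    # canonical gene order makes the linkage permutation-invariant
    order = np.argsort(np.array(genes, dtype=object))
    d = d[np.ix_(order, order)]
    ordered_genes = [genes[i] for i in order]
    link = hierarchy.linkage(squareform(d, checks=False), method="average")
    raw = hierarchy.fcluster(link, t=cut_height, criterion="distance")

    clusters: dict[int, list[str]] = {}
    for g, c in zip(ordered_genes, raw):
        clusters.setdefault(int(c), []).append(g)
    keep = [c for c, members in clusters.items() if len(members) >= min_module_size]
    keep.sort(key=lambda c: (-len(clusters[c]), min(clusters[c])))
    label_of: dict[int, str] = {c: f"M{i + 1}" for i, c in enumerate(keep)}
    if not keep:
        logger.warning("detect_modules: no cluster reached min_module_size=%d; "
                       "all genes unassigned", min_module_size)

    labels = {g: label_of.get(int(c), UNASSIGNED) for g, c in zip(ordered_genes, raw)}
    out = pd.DataFrame({"module": [labels[g] for g in genes]},
                       index=pd.Index(genes, name="gene_id"))
    out.attrs.update(min_module_size=min_module_size, cut_height=cut_height)
    return out


def module_enrichment(assignment: pd.DataFrame, gene_sets: FeatureNetwork) -> pd.DataFrame:
    """Fisher over-representation of each gene set within each module.

    The universe is the analyzed gene list (all genes in the assignment);
    BH q-values are computed per module across sets.  The unassigned label
    is skipped.
    """
    universe = frozenset(assignment.index)
    resolved = gene_sets.resolve(universe, min_size=1)
    n = len(universe)
    rows = []
    for module, sub in assignment.groupby("module"):
        if module == UNASSIGNED:
            continue
        members = frozenset(sub.index)
        for name in resolved.feature_ids():
            setg = resolved[name]
            a = len(setg & members)
            p = float(stats.hypergeom.sf(a - 1, n, len(setg), len(members)))
            rows.append((module, name, len(members), len(setg), a, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["module", "set_id", "module_size", "set_size",
                                      "overlap", "p"])
    if out.empty:
        out["q"] = pd.Series(dtype=float)
        return out
    out["q"] = np.nan
    for module, sub in out.groupby("module"):
        out.loc[sub.index, "q"] = adjust_q(sub["p"].to_numpy())
    return out


def scale_free_beta(expr_subset: pd.DataFrame, betas=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10),
                    r2_target: float = 0.8, n_bins: int = 10) -> int:
    """Smallest soft power whose degree distribution fits a power law.

    For each candidate beta the connectivity distribution is binned and the
    R^2 of the log10(frequency) ~ log10(mean connectivity) fit computed;
    the smallest beta reaching ``r2_target`` is returned (the largest
    candidate if none does, with a warning).
    """
    best = None
    for beta in betas:
        a = adjacency(expr_subset, beta=float(beta))
        k = a.to_numpy().sum(axis=1)
        k = k[k > 0]
        if k.size < n_bins:
            continue
        bins = np.quantile(k, np.linspace(0, 1, n_bins + 1))
        bins = np.unique(bins)
        if len(bins) < 3:
            continue
        which = np.clip(np.digitize(k, bins[1:-1]), 0, len(bins) - 2)
        freq = np.bincount(which, minlength=len(bins) - 1).astype(float)
        kmean = np.array([k[which == i].mean() if (which == i).any() else np.nan
                          for i in range(len(bins) - 1)])
        ok = (freq > 0) & np.isfinite(kmean) & (kmean > 0)
        if ok.sum() < 3:
            continue
        slope, intercept, r, *_ = stats.linregress(np.log10(kmean[ok]), np.log10(freq[ok]))
        if r**2 >= r2_target and slope < 0:
            return int(beta)
        best = int(beta)
    logger.warning("scale_free_beta: no beta reached R^2 >= %.2f; returning %s", r2_target, best)
    return best if best is not None else int(betas[-1])
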