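"""Reporter-feature scoring over gene-set and metabolic networks.

The reporter statistic asks whether the genes around a network feature (a
gene-set term, or a metabolite's enzyme neighborhood in a metabolic model)
show a coordinated transcriptional response, using the *whole* per-gene
p-value spectrum rather than a hard significance cut:

1. each gene's p-value is transformed to ``z = Phi^{-1}(1 - p)``;
2. a feature with k member genes scores ``z_raw = sum(z) / sqrt(k)``;
3. ``z_raw`` is corrected against a sampled background of random same-size
   gene sets from the universe: ``z_corrected = (z_raw - mu_k) / sigma_k``;
4. ``p_reporter = 1 - Phi(z_corrected)``.

The background correction removes the dependence on k and on the overall
shape of the study's p-value distribution, which is what lets features of
very different sizes be compared on one scale.  A classical one-sided
hypergeometric over-representation test is provided as the baseline the
aggregation approach is compared against: with diffuse signal (many member
genes shifted slightly, none individually significant) the aggregated
score retains power where the count-based test has none.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .differential import P_EPS
from .networks import FeatureNetwork
from .study import ExpressionStudy

logger = logging.getLogger(__name__)

__all__ = [
    "p_to_z", "directional_z", "metabolite_neighbors", "reporter_scores",
    "select_reporters", "x_scores", "hypergeometric_baseline",
]

DEFAULT_N_BG = 10_000
DEFAULT_CURRENCY_DEGREE_CUT = 50


def p_to_z(p_values) -> np.ndarray:
    """Inverse-normal transform ``z = Phi^{-1}(1 - p)``, monotone decreasing in p.

    p-values are clamped into ``[P_EPS, 1 - 1e-16]`` first so the result is
    always finite; inputs outside [0, 1] are rejected.
    """
    p = np.asarray(p_values, dtype=float)
    if np.isnan(p).any() or ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return stats.norm.isf(np.clip(p, P_EPS, 1.0 - 1e-16))


def directional_z(ttest_table: pd.DataFrame, side: str = "down") -> pd.Series:
    """z-scores from one-tailed gene-level p (distinct-directional scoring).

    Converts the two-sided t-test p to the one-tailed p for the requested
    direction (p/2 when the observed shift matches ``side``, 1 - p/2
    otherwise; exact for the symmetric t) and applies :func:`p_to_z`.
    Running the reporter separately on "down" and "up" z-vectors separates
    coherently repressed from coherently induced features, at the cost of
    missing mixed-direction ones.
    """
    if side not in ("down", "up"):
        raise ValueError("side must be 'down' or 'up'")
    sign = -1.0 if side == "down" else 1.0
    p_two = ttest_table["p_value"].to_numpy()
    matches = np.sign(ttest_table["t_stat"].to_numpy()) == sign
    p_one = np.where(matches, p_two / 2.0, 1.0 - p_two / 2.0)
    return pd.Series(p_to_z(p_one), index=ttest_table.index)


def metabolite_neighbors(model_triples: pd.DataFrame,
                         currency_degree_cut: int = DEFAULT_CURRENCY_DEGREE_CUT,
                         min_set_size: int = 2) -> FeatureNetwork:
    """Metabolite -> gene neighborhoods from gene-reaction-metabolite triples.

    A metabolite's neighbors are the genes of every reaction touching it.
    Metabolites attached to more than ``currency_degree_cut`` reactions are
    excluded (currency-metabolite filter: ubiquitous cofactors carry no
    pathway information); metabolites left with fewer than ``min_set_size``
    neighbor genes are excluded too.
    """
    has_gene = model_triples["gene_id"] != ""
    gene_rows = model_triples[has_gene]
    met_rows = model_triples[~has_gene]
    rxn_genes: dict[str, set[str]] = {}
    for rxn, sub in gene_rows.groupby("reaction_id"):
        rxn_genes[rxn] = set(sub["gene_id"])
    dangling = set(gene_rows["reaction_id"]) - set(met_rows["reaction_id"])
    if dangling:
        logger.warning("metabolite_neighbors: %d reactions have genes but no metabolites",
                       len(dangling))
    if met_rows.empty:
        logger.warning("metabolite_neighbors: empty model, returning empty network")
        return FeatureNetwork({}, kind="metabolite_bipartite", provenance="model")

    features: dict[str, frozenset[str]] = {}
    n_currency = 0
    for met, sub in met_rows.groupby("metabolite_id"):
        rxns = set(sub["reaction_id"])
        if len(rxns) > currency_degree_cut:
            n_currency += 1
            continue
        genes: set[str] = set()
        for rxn in rxns:
            genes |= rxn_genes.get(rxn, set())
        if len(genes) >= min_set_size:
            features[met] = frozenset(genes)
    if n_currency:
        logger.info("metabolite_neighbors: excluded %d currency-like metabolites "
                    "(reaction degree > %d)", n_currency, currency_degree_cut)
    return FeatureNetwork(features, kind="metabolite_bipartite", provenance="model")


# -- background sampling ------------------------------------------------------

def _background_moments(z: np.ndarray, sizes: np.ndarray, n_bg: int,
                        rng: np.random.Generator, chunk: int = 2000
                        ) -> dict[int, tuple[float, float]]:
    """Monte-Carlo mean/sd of z_raw for random k-subsets, per distinct k.

    Subsets are sampled uniformly *without* replacement: each background
    draw is a random permutation of the universe, whose first k elements
    form a uniform k-subset simultaneously for every k (so all set sizes
    share one RNG stream and the cost of one shuffle).  Sampled in chunks
    to bound memory.
    """
    n = z.size
    kmax = int(sizes.max())
    if kmax > n:
        raise ValueError("feature larger than gene universe")
    sums = np.empty((n_bg, kmax))
    done = 0
    while done < n_bg:
        m = min(chunk, n_bg - done)
        r = rng.random((m, n))
        part = np.argpartition(r, kmax - 1, axis=1)[:, :kmax]
        # order the kmax retained indices by their random keys so that the
        # first k columns are a uniform k-subset for every k <= kmax
        keys = np.take_along_axis(r, part, axis=1)
        order = np.argsort(keys, axis=1)
        idx = np.take_along_axis(part, order, axis=1)
        sums[done:done + m] = np.cumsum(z[idx], axis=1)
        done += m
    moments: dict[int, tuple[float, float]] = {}
    for k in np.unique(sizes):
        zr = sums[:, k - 1] / np.sqrt(k)
        mu = float(zr.mean())
        sigma = float(zr.std(ddof=1))
        if sigma == 0.0:
            raise ValueError(f"degenerate universe: zero background spread at k={k}")
        moments[int(k)] = (mu, sigma)
    return moments


def reporter_scores(z_by_gene: pd.Series, network: FeatureNetwork,
                    n_bg: int = DEFAULT_N_BG, min_set_size: int = 3,
                    seed: int = 0, log2fc_by_gene: pd.Series | None = None) -> pd.DataFrame:
    """Score every feature of a network for coordinated response.

    Parameters
    ----------
    z_by_gene:
        Per-gene z-scores over the full universe (``p_to_z`` of the
        gene-level p-values); the index defines the universe.
    network:
        Feature -> neighbor-gene mapping; members outside the universe are
        dropped, duplicate members collapse, and features with fewer than
        ``min_set_size`` resolvable members are skipped (logged).
    n_bg:
        Background subsets sampled per distinct member count.
    log2fc_by_gene:
        Optional per-gene log2 fold-changes; when given, each feature gets
        a direction label from the sign of its members' mean log2fc.

    Returns a DataFrame indexed by feature id with columns ``kind``, ``k``,
    ``z_raw``, ``z_corrected``, ``p_reporter``, ``direction``, ``members``;
    run metadata (n_bg, seed, min_set_size, universe size) in ``attrs``.
    Deterministic given the seed.
    """
    if n_bg < 1000:
        raise ValueError("n_bg must be at least 1000 for a stable background")
    z_by_gene = z_by_gene.astype(float)
    if not np.isfinite(z_by_gene.to_numpy()).all():
        raise ValueError("z values must be finite (clamp p before transforming)")
    universe = z_by_gene.index
    resolved = network.resolve(universe, min_size=min_set_size)
    n_skipped = len(network) - len(resolved)
    if n_skipped:
        logger.info("reporter_scores: skipped %d features below min_set_size=%d",
                    n_skipped, min_set_size)

    columns = ["kind", "k", "z_raw", "z_corrected", "p_reporter", "direction", "members"]
    if len(resolved) == 0:
        out = pd.DataFrame(columns=columns)
        out.index.name = "feature_id"
        out.attrs.update(n_bg=n_bg, seed=seed, min_set_size=min_set_size, universe=len(universe))
        return out

    z = z_by_gene.to_numpy()
    pos = {g: i for i, g in enumerate(universe)}
    names = resolved.feature_ids()
    sizes = np.array([len(resolved[f]) for f in names])
    rng = np.random.default_rng(seed)
    moments = _background_moments(z, sizes, n_bg, rng)

    rows = []
    for name, k in zip(names, sizes):
        members = sorted(resolved[name])
        z_raw = float(z[[pos[g] for g in members]].sum() / np.sqrt(k))
        mu, sigma = moments[int(k)]
        z_corr = (z_raw - mu) / sigma
        p_rep = float(stats.norm.sf(z_corr))
        if log2fc_by_gene is not None:
            mean_fc = float(log2fc_by_gene.reindex(members).mean())
            direction = "up" if mean_fc > 0 else ("down" if mean_fc < 0 else "mixed")
        else:
            direction = "na"
        rows.append((name, network.kind, int(k), z_raw, z_corr, p_rep, direction,
                     ";".join(members)))
    out = pd.DataFrame(rows, columns=["feature_id", *columns]).set_index("feature_id")
    out.attrs.update(n_bg=n_bg, seed=seed, min_set_size=min_set_size, universe=len(universe))
    return out


def select_reporters(result: pd.DataFrame, p_cut: float = 0.001) -> pd.DataFrame:
    """Features with reporter p strictly below ``p_cut``, ascending by p.

    Ties are broken by feature id so the ordering is stable.
    """
    hits = result[result["p_reporter"] < p_cut]
    # stable sort after an index sort -> ties broken by feature id
    return hits.sort_index(kind="mergesort").sort_values("p_reporter", kind="mergesort")


# -- X-scores -----------------------------------------------------------------

def x_scores(study: ExpressionStudy, features: FeatureNetwork | dict,
             grouping: str = "tissue_group") -> pd.DataFrame:
    """Normalized accumulated expression of each feature per sample group.

    Each gene row is standardized across all samples (mean 0, sd 1); the
    X-score of a feature in a group is the mean standardized value over
    (member genes x samples of the group).  ``grouping`` is either
    ``"tissue_group"`` (tissue x diet cells; 6 in the default design) or
    ``"tissue"`` (3).  Zero-variance gene rows are excluded with a log
    entry.  Because standardized rows average to zero, the size-weighted
    grand mean of a feature's X-scores over all groups is zero.
    """
    if grouping not in ("tissue_group", "tissue"):
        raise ValueError("grouping must be 'tissue_group' or 'tissue'")
    mapping = features.features if isinstance(features, FeatureNetwork) else features
    x = study.expression.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=1)
    keep = sd > 0
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("x_scores: excluded %d zero-variance gene rows", n_excluded)
    zmat = np.full_like(x, np.nan)
    zmat[keep] = (x[keep] - x[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    zdf = pd.DataFrame(zmat, index=study.gene_ids, columns=study.sample_ids)

    if grouping == "tissue_group":
        group_cols = {f"{t}|{g}": study.samples_where(tissue=t, group=g)
                      for t in study.tissues for g in study.groups}
    else:
        group_cols = {t: study.samples_where(tissue=t) for t in study.tissues}

    rows = {}
    for name in sorted(mapping):
        members = [g for g in mapping[name] if g in zdf.index and keep[study.gene_ids.get_loc(g)]]
        if not members:
            logger.warning("x_scores: feature %s has no usable member rows", name)
            continue
        sub = zdf.loc[members]
        rows[name] = {grp: float(sub[cols].to_numpy().mean()) for grp, cols in group_cols.items()}
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(group_cols))
    out.index.name = "feature_id"
    return out


# -- hypergeometric baseline --------------------------------------------------

def hypergeometric_baseline(sig_genes, universe, network: FeatureNetwork,
                            min_set_size: int = 1) -> pd.DataFrame:
    """Classical one-sided over-representation p per feature.

    ``p = P(overlap >= observed)`` under the hypergeometric null of drawing
    ``len(sig_genes)`` genes from the universe.  The comparison baseline
    for the aggregation-based reporter score: it only sees the hard
    significant/not dichotomy.
    """
    universe = frozenset(universe)
    sig = frozenset(sig_genes) & universe
    if len(sig) < len(frozenset(sig_genes)):
        logger.info("hypergeometric_baseline: %d significant genes outside universe dropped",
                    len(frozenset(sig_genes)) - len(sig))
    resolved = network.resolve(universe, min_size=min_set_size)
    n_univ = len(universe)
    rows = []
    for name in resolved.feature_ids():
        members = resolved[name]
        k = len(members)
        overlap = len(members & sig)
        p = float(stats.hypergeom.sf(overlap - 1, n_univ, k, len(sig)))
        rows.append((name, k, overlap, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["feature_id", "k", "overlap", "p_hyper"]
                       ).set_index("feature_id")
    return out
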