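"""Regulatory-driver analysis: target enrichment, co-occurrence, KS shifts.

Identifies transcription factors and microRNAs that plausibly drive an
observed expression change by testing whether their predicted targets are
over-represented among the responding genes (one-sided Fisher exact test,
FDR-corrected within regulator type), summarizing how much selected
regulators share targets (pairwise co-occurrence counts), and testing
whether a regulator's targets shift as a population (one-sided two-sample
Kolmogorov-Smirnov test on log2 fold-changes of targets vs. non-targets
— the natural readout for a repressor such as a microRNA, whose targets
should be collectively down-shifted).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .differential import adjust_q

logger = logging.getLogger(__name__)

__all__ = ["fisher_enrichment", "cooccurrence_matrix", "ks_target_shift"]


def fisher_enrichment(sig_genes, universe, target_map: dict[str, frozenset[str]],
                      reg_types: dict[str, str] | None = None) -> pd.DataFrame:
    """One-sided Fisher exact enrichment of each regulator's targets.

    Per regulator the 2x2 table (significant/not x target/not) over the
    universe is scored with the one-sided (over-representation) Fisher
    exact test, i.e. the hypergeometric upper tail.  The odds ratio uses
    a Haldane 0.5 correction when any cell is zero.  BH q-values are
    computed within regulator type when ``reg_types`` is given (TF and
    miRNA families corrected separately), otherwise over all regulators.

    Returns a DataFrame indexed by regulator id with the table counts
    (``a``: significant targets, ``b``: non-significant targets, ``c``:
    significant non-targets, ``d``: the rest), ``odds_ratio``, ``p`` and
    ``q``.
    """
    universe = frozenset(universe)
    n = len(universe)
    sig = frozenset(sig_genes) & universe
    if not sig:
        logger.warning("fisher_enrichment: empty significant set; all p = 1")
    rows = []
    for reg in sorted(target_map):
        targets = frozenset(target_map[reg]) & universe
        if not targets:
            logger.info("fisher_enrichment: regulator %s has no resolvable targets, dropped", reg)
            continue
        a = len(targets & sig)
        b = len(targets) - a
        c = len(sig) - a
        d = n - a - b - c
        # one-sided Fisher == hypergeometric upper tail at the observed overlap
        p = float(stats.hypergeom.sf(a - 1, n, len(targets), len(sig))) if sig else 1.0
        if min(a, b, c, d) == 0:
            orat = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            orat = (a * d) / (b * c)
        rtype = (reg_types or {}).get(reg, "all")
        rows.append((reg, rtype, a, b, c, d, orat, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["regulator_id", "type", "a", "b", "c", "d",
                                      "odds_ratio", "p"]).set_index("regulator_id")
    out["q"] = np.nan
    for rtype, sub in out.groupby("type"):
        out.loc[sub.index, "q"] = adjust_q(sub["p"].to_numpy())
    return out


def cooccurrence_matrix(selected_regulators, target_map: dict[str, frozenset[str]],
                        gene_scope) -> pd.DataFrame:
    """Pairwise shared-target counts within a gene scope.

    Entry (r1, r2) counts the scope genes targeted by both regulators; the
    diagonal is each regulator's target count within the scope.  The scope
    is typically the responding gene list under study (e.g. the
    downregulated members of the selected reporter terms).
    """
    regs = sorted(selected_regulators)
    scope = frozenset(gene_scope)
    scoped = {r: frozenset(target_map.get(r, frozenset())) & scope for r in regs}
    mat = np.zeros((len(regs), len(regs)), dtype=int)
    for i, r1 in enumerate(regs):
        for j, r2 in enumerate(regs[i:], start=i):
            c = len(scoped[r1] & scoped[r2])
            mat[i, j] = mat[j, i] = c
    return pd.DataFrame(mat, index=pd.Index(regs, name="regulator_id"), columns=regs)


def ks_target_shift(log2fc_by_gene: pd.Series, target_set, side: str = "down",
                    seed: int = 0, n_perm: int = 10_000,
                    small_n: int = 5) -> tuple[float, float]:
    """One-sided two-sample KS test of target vs. non-target fold-changes.

    ``side="down"`` tests the alternative that the targets' log2
    fold-changes are stochastically *smaller* than the non-targets'
    (collective repression); ``side="up"`` tests the opposite shift.
    Returns the one-sided KS statistic D and its p-value (asymptotic; an
    exact seeded permutation p when either group has fewer than
    ``small_n`` members).
    """
    if side not in ("down", "up"):
        raise ValueError("side must be 'down' or 'up'")
    fc = log2fc_by_gene.astype(float)
    targets = fc.index.isin(frozenset(target_set))
    x_t = fc.to_numpy()[targets]
    x_n = fc.to_numpy()[~targets]
    if x_t.size == 0 or x_n.size == 0:
        raise ValueError("both target and non-target groups must be non-empty")
    # scipy's 'greater' alternative: CDF(targets) > CDF(rest), i.e. targets
    # shifted toward smaller values
    alternative = "greater" if side == "down" else "less"
    if min(x_t.size, x_n.size) < small_n:
        d_obs = _one_sided_ks_d(x_t, x_n, side)
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([x_t, x_n])
        count = 0
        for _ in range(n_perm):
            rng.shuffle(pooled)
            if _one_sided_ks_d(pooled[:x_t.size], pooled[x_t.size:], side) >= d_obs:
                count += 1
        return float(d_obs), (count + 1) / (n_perm + 1)
    res = stats.ks_2samp(x_t, x_n, alternative=alternative, method="asymp")
    return float(res.statistic), float(res.pvalue)


def _one_sided_ks_d(x: np.ndarray, y: np.ndarray, side: str) -> float:
    """One-sided KS statistic via ECDF evaluation at the pooled points."""
    grid = np.concatenate([x, y])
    fx = np.searchsorted(np.sort(x), grid, side="right") / x.size
    fy = np.searchsorted(np.sort(y), grid, side="right") / y.size
    diff = fx - fy if side == "down" else fy - fx
    return float(max(diff.max(), 0.0))
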