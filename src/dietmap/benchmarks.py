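"""Validation studies: calibration and planted-signal recovery at desk scale.

Each function runs one self-contained study on synthetic data with planted
truth and returns a small dict of summary numbers.  They are what the
acceptance checks and the reproduction script execute; problem sizes are
chosen so every study runs in seconds to a few minutes on one CPU.

Seeding: every study takes a single ``seed``; per-run seeds are derived
deterministically from it and stay below 2**31.
"""

from __future__ import annotations

import hashlib
import json
import shutil
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import coexpression, differential, pipeline, regulation, reporter
from .networks import FeatureNetwork
from .simulate import (SimulationConfig, generate_expression, generate_gene_sets,
                       generate_regulator_targets)

__all__ = [
    "derive_seed", "reporter_null_calibration", "reporter_recovery_study",
    "svd_structure_check", "module_recovery_study", "module_recovery_grid",
    "regulator_recovery_study", "regulator_null_calibration", "demo_determinism",
]


def derive_seed(seed: int, i: int) -> int:
    """Deterministic per-run sub-seed, always below 2**31."""
    h = hashlib.sha256(f"{seed}:{i}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


# -- reporter calibration and recovery ---------------------------------------

def reporter_null_calibration(n_genes: int = 2000, n_features: int = 2000,
                              size_range: tuple[int, int] = (5, 50),
                              n_bg: int = 10_000, seed: int = 0) -> dict:
    """Reporter p-values on a null universe must be uniform.

    Universe z drawn standard normal; features are random gene subsets of
    sizes in ``size_range``.  Returns the KS statistic and p against
    Uniform(0,1) and the fraction of reporter p below 0.05.
    """
    rng = np.random.default_rng(derive_seed(seed, 0))
    genes = [f"G{i:05d}" for i in range(n_genes)]
    z = pd.Series(rng.standard_normal(n_genes), index=genes)
    sizes = rng.integers(size_range[0], size_range[1] + 1, size=n_features)
    features = {
        f"F{i:05d}": frozenset(rng.choice(genes, size=int(k), replace=False))
        for i, k in enumerate(sizes)
    }
    network = FeatureNetwork(features, kind="gene_set_collection", provenance="null")
    res = reporter.reporter_scores(z, network, n_bg=n_bg, min_set_size=1,
                                   seed=derive_seed(seed, 1))
    p = res["p_reporter"].to_numpy()
    ks = stats.kstest(p, "uniform")
    return {
        "n_features": int(len(p)),
        "ks_stat": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "frac_p_lt_05": float((p < 0.05).mean()),
    }


def _planted_ranks(res: pd.DataFrame, p_col: str, planted_ids: list[str]) -> list[float]:
    ranks = pd.Series(stats.rankdata(res[p_col].to_numpy(), method="average"),
                      index=res.index)
    return [float(ranks[fid]) for fid in planted_ids if fid in ranks.index]


def reporter_recovery_study(n_runs: int = 20, seed: int = 0,
                            diet_effect_size: float = 0.5, noise_sd: float = 0.3,
                            n_bg: int = 10_000, p_cut: float = 0.001) -> dict:
    """Recovery of planted sets in the diffuse-signal regime.

    Per run: simulate the default three-tissue study (planted member genes
    shifted by a diffuse ``diet_effect_size`` that leaves most individual
    genes non-significant), score the gene-set collection per tissue with
    the reporter statistic, and check that every planted set passes the
    ``p < p_cut`` selection.  Also compares the planted sets' median rank
    under the reporter score vs. the hypergeometric baseline fed with the
    per-gene Q < 0.05 list.
    """
    all_selected = 0
    rep_ranks: list[float] = []
    hyp_ranks: list[float] = []
    for r in range(n_runs):
        cfg = SimulationConfig(diet_effect_size=diet_effect_size, noise_sd=noise_sd,
                               seed=derive_seed(seed, 100 + r))
        study, truth = generate_expression(cfg)
        study = study.with_expression(differential.quantile_normalize(study.expression))
        sets, _ = generate_gene_sets(cfg)
        run_ok = True
        for t_i, tissue in enumerate(study.tissues):
            tab = differential.per_tissue_ttest(study, tissue)
            z = pd.Series(reporter.p_to_z(tab["p_value"]), index=tab.index)
            res = reporter.reporter_scores(z, sets, n_bg=n_bg, min_set_size=3,
                                           seed=derive_seed(seed, 1000 + 10 * r + t_i))
            sel = set(reporter.select_reporters(res, p_cut).index)
            planted_ids = [ps.set_id for ps in truth.planted_sets[tissue]]
            if not all(pid in sel for pid in planted_ids):
                run_ok = False
            rep_ranks += _planted_ranks(res, "p_reporter", planted_ids)
            sig = differential.significant_genes(tab, 0.05)
            hyp = reporter.hypergeometric_baseline(sig, tab.index, sets, min_set_size=3)
            hyp_ranks += _planted_ranks(hyp, "p_hyper", planted_ids)
        all_selected += run_ok
    return {
        "n_runs": n_runs,
        "all_planted_selected_rate": all_selected / n_runs,
        "median_rank_reporter": float(np.median(rep_ranks)),
        "median_rank_hypergeometric": float(np.median(hyp_ranks)),
    }


# -- SVD structure ------------------------------------------------------------

def svd_structure_check(seed: int = 0, tissue_effect_sd: float = 2.0,
                        diet_effect_size: float = 0.5) -> dict:
    """Tissue identity must dominate the leading components.

    With a tissue effect several times the diet effect, the component-1
    sample coordinates must separate the tissues with zero range overlap,
    and the tissue between-group variance fraction on component 1 must
    exceed any within-tissue diet separation seen on components 1-2.
    """
    cfg = SimulationConfig(tissue_effect_sd=tissue_effect_sd,
                           diet_effect_size=diet_effect_size, seed=derive_seed(seed, 0))
    study, _ = generate_expression(cfg)
    study = study.with_expression(differential.quantile_normalize(study.expression))
    svd = differential.svd_overview(study)
    load = svd.sample_loadings
    meta = study.samples

    pc1 = load["PC1"]
    ranges = {t: (pc1[meta["tissue"] == t].min(), pc1[meta["tissue"] == t].max())
              for t in study.tissues}
    sorted_r = sorted(ranges.values())
    tissue_sep = all(sorted_r[i][1] < sorted_r[i + 1][0] for i in range(len(sorted_r) - 1))

    def eta2(values: pd.Series, labels: pd.Series) -> float:
        grand = values.mean()
        between = sum(len(v) * (v.mean() - grand) ** 2 for _, v in values.groupby(labels))
        total = ((values - grand) ** 2).sum()
        return float(between / total) if total > 0 else 0.0

    diet_eta = max(
        eta2(load.loc[meta["tissue"] == t, pc], meta.loc[meta["tissue"] == t, "group"])
        for t in study.tissues for pc in ("PC1", "PC2")
    )
    tissue_eta = eta2(pc1, meta["tissue"])
    return {
        "tissue_zero_overlap_pc1": float(tissue_sep),
        "max_within_tissue_diet_eta2_pc12": diet_eta,
        "tissue_eta2_pc1": tissue_eta,
        "tissue_dominates_diet": float(tissue_eta > diet_eta),
        "pc1_variance_fraction": float(svd.variance_fraction[0]),
    }


# -- co-expression module recovery --------------------------------------------

def _module_config(block_correlation: float, seed: int, n_noise: int = 60,
                   block_size: int = 30, n_blocks: int = 2) -> SimulationConfig:
    """Dedicated co-expression design: planted blocks among unstructured genes.

    No tissue or diet offsets, so the network reflects pure replicate-level
    covariation: the regime in which block recovery is well defined.
    """
    return SimulationConfig(
        n_genes=n_blocks * block_size + n_noise,
        n_coexpr_blocks=n_blocks, block_size=block_size,
        block_correlation=block_correlation,
        tissue_effect_sd=0.0, diet_effect_size=0.0,
        n_gene_sets=5, n_planted_sets_per_tissue=0, set_size_range=(5, 20),
        seed=seed,
    )


def _block_jaccards(cfg: SimulationConfig, beta: float = 6.0, cut_height: float = 0.85,
                    min_module_size: int = 10) -> list[float]:
    study, truth = generate_expression(cfg)
    adj = coexpression.adjacency(study.expression, beta=beta)
    tom_m = coexpression.tom(adj)
    modules = coexpression.detect_modules(tom_m, min_module_size=min_module_size,
                                          cut_height=cut_height)
    module_members = {m: set(sub.index) for m, sub in modules.groupby("module")
                      if m != coexpression.UNASSIGNED}
    out = []
    for genes in truth.coexpr_blocks.values():
        gset = set(genes)
        out.append(max((len(gset & mm) / len(gset | mm) for mm in module_members.values()),
                       default=0.0))
    return out


def module_recovery_study(n_runs: int = 20, seed: int = 0,
                          block_correlation: float = 0.8,
                          jaccard_cut: float = 0.9) -> dict:
    """Planted-block recovery rate of the TOM module detector."""
    n_recovered = 0
    jaccards: list[float] = []
    for r in range(n_runs):
        jac = _block_jaccards(_module_config(block_correlation, derive_seed(seed, 200 + r)))
        jaccards += jac
        n_recovered += all(j >= jaccard_cut for j in jac)
    return {
        "n_runs": n_runs,
        "recovery_rate": n_recovered / n_runs,
        "median_jaccard": float(np.median(jaccards)),
    }


def module_recovery_grid(correlations=(0.8, 0.6, 0.4), n_runs: int = 10,
                         seed: int = 0) -> dict:
    """Median block Jaccard along a correlation grid (should not increase
    as the planted correlation weakens)."""
    out = {}
    for rho in correlations:
        jacs: list[float] = []
        for r in range(n_runs):
            jacs += _block_jaccards(_module_config(rho, derive_seed(seed, 300 + r)))
        out[str(rho)] = float(np.median(jacs))
    return out


# -- regulator recovery and calibration ---------------------------------------

def regulator_recovery_study(n_runs: int = 100, seed: int = 0) -> dict:
    """Recovery of planted regulators by Fisher enrichment and the KS shift.

    Fisher: per run, the responding gene list is the planted down-shifted
    gene set of each planted regulator's tissue; recovery means the
    regulator reaches q < 0.05 within its type.  KS: per run, one planted
    repressor's targets must show a significant downward fold-change shift
    (p < 0.05) in its tissue.  The KS leg simulates the expression matrix;
    the Fisher leg needs only the target table.
    """
    fisher_hits = 0
    fisher_total = 0
    ks_hits = 0
    for r in range(n_runs):
        cfg = SimulationConfig(seed=derive_seed(seed, 400 + r))
        table, truth = generate_regulator_targets(cfg)
        universe = [f"G{i:05d}" for i in range(cfg.n_genes)]
        target_map = {reg: frozenset(sub["gene_id"]) for reg, sub in table.groupby("regulator_id")}
        reg_types = dict(table.drop_duplicates("regulator_id")
                         .set_index("regulator_id")["type"])
        for pr in truth.planted_regulators:
            sig = truth.perturbed_genes(pr.tissue, pr.direction)
            enr = regulation.fisher_enrichment(sig, universe, target_map, reg_types)
            fisher_total += 1
            fisher_hits += bool(enr.loc[pr.regulator_id, "q"] < 0.05)

        study, truth_e = generate_expression(cfg)
        mirna = next(p for p in truth_e.planted_regulators if p.reg_type == "miRNA")
        tab = differential.per_tissue_ttest(study, mirna.tissue)
        _d, p = regulation.ks_target_shift(tab["log2fc"], target_map[mirna.regulator_id],
                                           side="down", seed=derive_seed(seed, 500 + r))
        ks_hits += bool(p < 0.05)
    return {
        "n_runs": n_runs,
        "fisher_recovery_rate": fisher_hits / fisher_total,
        "ks_detection_rate": ks_hits / n_runs,
    }


def regulator_null_calibration(n_runs: int = 100, seed: int = 0,
                               n_sig: int = 500) -> dict:
    """Type-I error of the enrichment and KS tests under null configs.

    Fisher: no planted regulators, responding list drawn at random; the
    fraction of regulator tests with p < 0.05 estimates the level (the
    moderate list size keeps the hypergeometric support fine enough for
    the discrete test to approach its nominal level).  KS: expression with
    zero diet effect; each regulator's targets are random, so the target
    shift test sees exchangeable groups.
    """
    fisher_p: list[float] = []
    ks_p: list[float] = []
    for r in range(n_runs):
        cfg = SimulationConfig(n_planted_regulators=0, seed=derive_seed(seed, 600 + r))
        table, _ = generate_regulator_targets(cfg)
        universe = [f"G{i:05d}" for i in range(cfg.n_genes)]
        rng = np.random.default_rng(derive_seed(seed, 700 + r))
        sig = rng.choice(universe, size=n_sig, replace=False)
        target_map = {reg: frozenset(sub["gene_id"]) for reg, sub in table.groupby("regulator_id")}
        enr = regulation.fisher_enrichment(sig, universe, target_map)
        fisher_p += list(enr["p"])

        cfg_null = SimulationConfig(diet_effect_size=0.0, n_planted_regulators=0,
                                    seed=derive_seed(seed, 800 + r))
        study, _ = generate_expression(cfg_null)
        tab = differential.per_tissue_ttest(study, study.tissues[0])
        for reg in sorted(target_map):
            _d, p = regulation.ks_target_shift(tab["log2fc"], target_map[reg], side="down")
            ks_p.append(p)
    return {
        "n_fisher_tests": len(fisher_p),
        "fisher_frac_p_lt_05": float(np.mean(np.asarray(fisher_p) < 0.05)),
        "n_ks_tests": len(ks_p),
        "ks_frac_p_lt_05": float(np.mean(np.asarray(ks_p) < 0.05)),
    }


# -- end-to-end determinism ----------------------------------------------------

def demo_determinism(seed: int = 0, workdir: str | Path | None = None) -> dict:
    """Run the built-in demo twice under the same seed; manifests must match."""
    base = Path(workdir) if workdir else Path(tempfile.mkdtemp(prefix="dietmap_demo_"))
    cleanup = workdir is None
    try:
        manifests = []
        for tag in ("a", "b"):
            out = base / tag
            result = pipeline.run_pipeline(pipeline.demo_config(out, seed=seed))
            manifests.append(json.dumps(
                {"parameters": result["manifest"]["parameters"] | {"outdir": ""},
                 "outputs": result["manifest"]["outputs"]}, sort_keys=True))
        n_outputs = len(json.loads(manifests[0])["outputs"])
        return {"identical": float(manifests[0] == manifests[1]), "n_outputs": n_outputs}
    finally:
        if cleanup:
            shutil.rmtree(base, ignore_errors=True)
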