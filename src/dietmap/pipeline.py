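"""End-to-end orchestration of the multi-tissue integrative analysis.

Runs, from one config: quantile normalization -> SVD overview -> per-tissue
diet t-tests + two-way ANOVA -> FDR adjustment and genome-ordered export ->
reporter scoring on three networks (gene-set collection in the GO role, a
second collection in the Reactome role, metabolite neighborhoods from the
metabolic model) -> X-score summaries -> regulator target enrichment,
co-occurrence and KS target-shift tests -> co-expression modules on the
diet-responsive gene list with module-level functional enrichment.

Every stage writes a TSV under the output directory and is logged with its
input/output shapes; a run manifest records parameters, per-stage seeds and
sha256 checksums of every output so a rerun can be verified byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, coexpression, differential, io, regulation, reporter
from .networks import FeatureNetwork
from .simulate import (SimulationConfig, SyntheticTruth, generate_expression,
                       generate_gene_sets, generate_metabolic_model,
                       generate_regulator_targets, generate_secondary_gene_sets)
from .study import ExpressionStudy

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "validate_inputs", "demo_config"]


class PipelineError(RuntimeError):
    """Stage failure with a machine-readable stage name and error code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    """Everything a run needs: either file inputs or a simulation config."""

    outdir: str | Path = "dietmap_run"
    simulation: SimulationConfig | None = None
    # file inputs (used when simulation is None)
    expression_path: str | None = None
    metadata_path: str | None = None
    annotation_path: str | None = None
    gmt_primary_path: str | None = None      # GO role
    gmt_secondary_path: str | None = None    # Reactome role
    model_triples_path: str | None = None
    regulator_targets_path: str | None = None

    # stage parameters
    q_cut: float = 0.05                  # per-gene significance cut on Q
    reporter_p_cut: float = 0.001        # reporter feature selection cut
    n_bg: int = 10_000                   # background subsets per distinct set size
    min_set_size: int = 3                # gene-set collections
    min_metabolite_size: int = 2         # metabolite neighborhoods
    currency_degree_cut: int = 50
    xscore_grouping: str = "tissue_group"
    q_method: str = "bh"                 # FDR method: "bh" or "storey"
    reporter_input: str = "p"            # gene-level statistic: "p" or "q"
    beta: float = 6.0                    # soft-threshold power
    cut_height: float = 0.85             # static cut on 1 - TOM
    min_module_size: int = 10
    coexpr_q_cut: float = 0.05           # ANOVA diet-factor cut for the network gene list
    coexpr_top_n: int = 150              # fallback list size when too few genes pass
    center_within_tissue: bool = True    # remove tissue offsets before co-expression
    seed: int = 0

    def __post_init__(self) -> None:
        file_inputs = [self.expression_path, self.metadata_path]
        if self.simulation is not None and any(p is not None for p in file_inputs):
            raise ValueError("specify either a simulation config or file inputs, not both")
        if self.simulation is None and any(p is None for p in file_inputs):
            raise ValueError("file-input runs need at least expression and metadata paths")
        for name, lo, hi in (("q_cut", 0, 1), ("reporter_p_cut", 0, 1), ("coexpr_q_cut", 0, 1)):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name} must lie in [{lo}, {hi}]")
        if self.cut_height <= 0 or self.cut_height > 1:
            raise ValueError("cut_height must lie in (0, 1]")

    def stage_seed(self, stage: str) -> int:
        """Named, logged per-stage seed derived from the master seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        s = int.from_bytes(h[:4], "big") % (2**31)
        logger.info("stage %s: seed %d", stage, s)
        return s


def demo_config(outdir, seed: int = 0) -> PipelineConfig:
    """Built-in synthetic demo mirroring the three-tissue two-diet design.

    Uses a larger planted diet effect than the generator default so the
    per-gene significance stages have recoverable hits at n = 3 vs 3, and
    carves the co-expression blocks out of planted sets so the module stage
    operates on diet-responsive genes, as in the motivating study.
    """
    sim = SimulationConfig(
        n_genes=2000,
        diet_effect_size=2.0,
        blocks_from_planted=True,
        set_size_range=(30, 50),
        seed=int(seed),
    )
    return PipelineConfig(outdir=outdir, simulation=sim, seed=int(seed))


# -- validation ---------------------------------------------------------------

def validate_inputs(paths: dict[str, str]) -> list[dict]:
    """Schema and cross-reference checks on a file-input bundle.

    Returns a list of violations, each ``{"file", "severity", "message"}``;
    fatal ones mean the pipeline would abort.  An empty list is a clean
    bundle.
    """
    violations: list[dict] = []

    def fatal(file, message):
        violations.append({"file": str(file), "severity": "fatal", "message": message})

    study = None
    try:
        study = io.read_expression_study(paths["expression"], paths["metadata"],
                                         paths.get("annotation"))
    except Exception as exc:  # noqa: BLE001 - report, don't crash
        fatal(paths.get("expression", "?"), f"cannot load expression study: {exc}")

    if study is not None:
        # the study container silently restricts metadata to matrix columns,
        # so compare against the raw metadata file
        raw_meta = pd.read_csv(paths["metadata"], sep="\t", dtype={"sample_id": str})
        extra = set(raw_meta["sample_id"]) - set(study.expression.columns)
        if extra:
            fatal(paths["metadata"], f"metadata samples missing from matrix: {sorted(extra)[:5]}")

    for key, reader in (("gmt_primary", io.read_gmt), ("gmt_secondary", io.read_gmt),
                        ("model_triples", io.read_model_triples),
                        ("regulator_targets", io.read_regulator_targets)):
        path = paths.get(key)
        if path is None:
            continue
        try:
            obj = reader(path)
        except Exception as exc:  # noqa: BLE001
            fatal(path, str(exc))
            continue
        if study is not None:
            genes = set(study.gene_ids)
            if key in ("gmt_primary", "gmt_secondary"):
                members = set().union(*obj.features.values()) if len(obj) else set()
                missing = members - genes
                if members and len(missing) == len(members):
                    fatal(path, "no gene-set member resolves against the expression matrix")
                elif missing:
                    violations.append({"file": str(path), "severity": "warning",
                                       "message": f"{len(missing)} set members not in matrix"})
            elif key == "regulator_targets":
                missing = set(obj["gene_id"]) - genes
                if missing:
                    violations.append({"file": str(path), "severity": "warning",
                                       "message": f"{len(missing)} target genes not in matrix"})
    return violations


# -- helpers ------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, outputs: dict, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)
    outputs[path.name] = path


def _center_within_tissue(study: ExpressionStudy, matrix: pd.DataFrame) -> pd.DataFrame:
    out = matrix.copy()
    for tissue in study.tissues:
        cols = [c for c in matrix.columns if c in set(study.samples_where(tissue=tissue))]
        out[cols] = matrix[cols].sub(matrix[cols].mean(axis=1), axis=0)
    return out


# -- the pipeline -------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns {"outputs": {name: path}, "manifest": dict}.

    Any stage failure raises :class:`PipelineError` carrying the stage name;
    outputs written before the failure are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    truth: SyntheticTruth | None = None

    # stage: inputs -----------------------------------------------------------
    try:
        if config.simulation is not None:
            sim = config.simulation
            study, truth = generate_expression(sim)
            go_sets, _ = generate_gene_sets(sim)
            reactome_sets = generate_secondary_gene_sets(sim)
            _met_network, triples = generate_metabolic_model(sim)
            reg_table, _ = generate_regulator_targets(sim)
            inputs_dir = outdir / "inputs"
            inputs_dir.mkdir(exist_ok=True)
            io.write_expression_study(study, inputs_dir / "expression.tsv",
                                      inputs_dir / "samples.tsv", inputs_dir / "genes.tsv")
            io.write_gmt(go_sets, inputs_dir / "go_sets.gmt")
            io.write_gmt(reactome_sets, inputs_dir / "reactome_sets.gmt")
            io.write_model_triples(triples, inputs_dir / "model_triples.tsv")
            io.write_regulator_targets(reg_table, inputs_dir / "regulator_targets.tsv")
            for p in inputs_dir.iterdir():
                outputs[f"inputs/{p.name}"] = p
        else:
            study = io.read_expression_study(config.expression_path, config.metadata_path,
                                             config.annotation_path)
            go_sets = (io.read_gmt(config.gmt_primary_path, provenance="primary")
                       if config.gmt_primary_path else None)
            reactome_sets = (io.read_gmt(config.gmt_secondary_path, provenance="secondary")
                             if config.gmt_secondary_path else None)
            triples = (io.read_model_triples(config.model_triples_path)
                       if config.model_triples_path else None)
            reg_table = (io.read_regulator_targets(config.regulator_targets_path)
                         if config.regulator_targets_path else None)
        logger.info("stage inputs: %d genes x %d samples, tissues=%s",
                    *study.expression.shape, study.tissues)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("inputs", "load_failed", str(exc)) from exc

    # stage: normalize --------------------------------------------------------
    try:
        normalized = differential.quantile_normalize(study.expression)
        study = study.with_expression(normalized)
        _write(normalized, outdir / "normalized_expression.tsv", outputs)
    except Exception as exc:
        raise PipelineError("normalize", "failed", str(exc)) from exc

    # stage: svd --------------------------------------------------------------
    try:
        svd = differential.svd_overview(study)
        _write(svd.to_frame(), outdir / "svd_summary.tsv", outputs)
        _write(svd.sample_loadings, outdir / "svd_loadings.tsv", outputs)
    except Exception as exc:
        raise PipelineError("svd", "failed", str(exc)) from exc

    # stage: differential -----------------------------------------------------
    try:
        ttests = {t: differential.per_tissue_ttest(study, t, q_method=config.q_method)
                  for t in study.tissues}
        for tissue, table in ttests.items():
            _write(table, outdir / f"ttest_{tissue}.tsv", outputs)
        anova = differential.two_way_anova(study, q_method=config.q_method)
        _write(anova, outdir / "anova.tsv", outputs)
        if study.genes is not None:
            circular = differential.circular_map_export(ttests, study.genes)
            _write(circular, outdir / "circular_map.tsv", outputs, index=False)
        sig_union = set().union(*(differential.significant_genes(t, config.q_cut)
                                  for t in ttests.values()))
        if sig_union:
            _write(differential.sample_distances(study, sorted(sig_union)),
                   outdir / "sample_distances.tsv", outputs)
        logger.info("stage differential: significant at Q<%g per tissue: %s", config.q_cut,
                    {t: len(differential.significant_genes(tab, config.q_cut))
                     for t, tab in ttests.items()})
    except Exception as exc:
        raise PipelineError("differential", "failed", str(exc)) from exc

    # stage: reporter ---------------------------------------------------------
    networks: dict[str, FeatureNetwork] = {}
    if go_sets is not None:
        networks["go"] = go_sets
    if reactome_sets is not None:
        networks["reactome"] = reactome_sets
    if triples is not None:
        networks["metabolites"] = reporter.metabolite_neighbors(
            triples, currency_degree_cut=config.currency_degree_cut,
            min_set_size=config.min_metabolite_size)
    reporter_tables: dict[str, pd.DataFrame] = {}
    selected_go: dict[str, pd.DataFrame] = {}
    try:
        for role, network in networks.items():
            min_size = (config.min_metabolite_size if network.kind == "metabolite_bipartite"
                        else config.min_set_size)
            per_tissue = []
            for tissue in study.tissues:
                tab = ttests[tissue]
                stat_col = "q_value" if config.reporter_input == "q" else "p_value"
                z = pd.Series(reporter.p_to_z(tab[stat_col]), index=tab.index)
                res = reporter.reporter_scores(
                    z, network, n_bg=config.n_bg, min_set_size=min_size,
                    seed=config.stage_seed(f"reporter:{role}:{tissue}"),
                    log2fc_by_gene=tab["log2fc"])
                res = res.drop(columns=["members"])
                res.insert(0, "tissue", tissue)
                per_tissue.append(res.reset_index())
                if role == "go":
                    selected_go[tissue] = reporter.select_reporters(res, config.reporter_p_cut)
            table = pd.concat(per_tissue, ignore_index=True)
            reporter_tables[role] = table
            _write(table, outdir / f"reporter_{role}.tsv", outputs, index=False)
            logger.info("stage reporter[%s]: %d features x %d tissues scored",
                        role, len(network), len(study.tissues))
    except Exception as exc:
        raise PipelineError("reporter", "failed", str(exc)) from exc

    # stage: xscores ----------------------------------------------------------
    try:
        if "go" in networks and selected_go:
            chosen = sorted(set().union(*(set(s.index) for s in selected_go.values())))
            if chosen:
                sub = FeatureNetwork({f: networks["go"][f] for f in chosen},
                                     kind="gene_set_collection", provenance="selected")
                xs = reporter.x_scores(study, sub, grouping=config.xscore_grouping)
                _write(xs, outdir / "xscores_go.tsv", outputs)
            else:
                logger.warning("stage xscores: no reporter feature passed p<%g",
                               config.reporter_p_cut)
    except Exception as exc:
        raise PipelineError("xscores", "failed", str(exc)) from exc

    # stage: regulation -------------------------------------------------------
    try:
        if reg_table is not None:
            universe = list(study.gene_ids)
            target_map = io.targets_by_regulator(reg_table, universe=universe)
            reg_types = dict(reg_table.drop_duplicates("regulator_id")
                             .set_index("regulator_id")["type"])
            enr_rows, ks_rows = [], []
            for tissue in study.tissues:
                # responding genes: members of the selected reporter terms
                sel = selected_go.get(tissue)
                members: set[str] = set()
                down_members: set[str] = set()
                if sel is not None and len(sel):
                    for fid in sel.index:
                        genes_f = networks["go"][fid] & set(universe)
                        members |= genes_f
                        fc = ttests[tissue]["log2fc"].reindex(sorted(genes_f))
                        down_members |= set(fc.index[fc < 0])
                if not members:  # fall back to per-gene significance
                    members = differential.significant_genes(ttests[tissue], config.q_cut)
                    fc = ttests[tissue]["log2fc"].reindex(sorted(members))
                    down_members = set(fc.index[fc < 0])
                enr = regulation.fisher_enrichment(members, universe, target_map, reg_types)
                enr.insert(0, "tissue", tissue)
                enr_rows.append(enr.reset_index())
                selected_regs = sorted(enr.index[enr["q"] < 0.05])
                if selected_regs:
                    co = regulation.cooccurrence_matrix(selected_regs, target_map, down_members)
                    _write(co, outdir / f"cooccurrence_{tissue}.tsv", outputs)
                ks_seed = config.stage_seed(f"ks:{tissue}")
                for reg in sorted(target_map):
                    d, p = regulation.ks_target_shift(ttests[tissue]["log2fc"],
                                                      target_map[reg], side="down", seed=ks_seed)
                    ks_rows.append((tissue, reg, reg_types.get(reg, "all"), d, p))
            _write(pd.concat(enr_rows, ignore_index=True),
                   outdir / "regulator_enrichment.tsv", outputs, index=False)
            _write(pd.DataFrame(ks_rows, columns=["tissue", "regulator_id", "type", "D", "p"]),
                   outdir / "ks_targets.tsv", outputs, index=False)
    except Exception as exc:
        raise PipelineError("regulation", "failed", str(exc)) from exc

    # stage: coexpression -----------------------------------------------------
    try:
        diet_genes = coexpression.select_diet_genes(anova, config.coexpr_q_cut)
        if len(diet_genes) < 2 * config.min_module_size:
            logger.warning("stage coexpression: only %d genes at q<%g; "
                           "falling back to top %d by diet p", len(diet_genes),
                           config.coexpr_q_cut, config.coexpr_top_n)
            diet_genes = sorted(anova["p_diet"].nsmallest(config.coexpr_top_n).index)
        expr_sub = study.expression.loc[diet_genes]
        if config.center_within_tissue:
            expr_sub = _center_within_tissue(study, expr_sub)
        adj = coexpression.adjacency(expr_sub, beta=config.beta)
        tom_m = coexpression.tom(adj)
        _write(tom_m, outdir / "tom.tsv", outputs)
        modules = coexpression.detect_modules(tom_m, min_module_size=config.min_module_size,
                                              cut_height=config.cut_height)
        _write(modules, outdir / "modules.tsv", outputs)
        if go_sets is not None:
            menr = coexpression.module_enrichment(modules, go_sets)
            _write(menr, outdir / "module_enrichment.tsv", outputs, index=False)
        sizes = modules["module"].value_counts().to_dict()
        logger.info("stage coexpression: %d genes, modules %s", len(diet_genes), sizes)
    except Exception as exc:
        raise PipelineError("coexpression", "failed", str(exc)) from exc

    # stage: recovery (simulation runs only) ----------------------------------
    if truth is not None:
        recovery = _recovery_report(truth, selected_go, locals().get("modules"),
                                    enr_rows if reg_table is not None else None)
        with open(outdir / "recovery.json", "w") as fh:
            json.dump(recovery, fh, indent=2, sort_keys=True)
        outputs["recovery.json"] = outdir / "recovery.json"

    # manifest ---------------------------------------------------------------
    manifest = {
        "package_version": __version__,
        "parameters": _jsonable_config(config),
        "outputs": {name: _sha256(path) for name, path in sorted(outputs.items())},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {"outputs": outputs, "manifest": manifest}


def _jsonable_config(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["outdir"] = str(d["outdir"])
    return d


def _recovery_report(truth: SyntheticTruth, selected_go, modules, enr_rows) -> dict:
    """Planted truth vs. pipeline outputs, per signal type."""
    report: dict = {}
    planted_total = sum(len(v) for v in truth.planted_sets.values())
    found = 0
    for tissue, planted in truth.planted_sets.items():
        sel = selected_go.get(tissue)
        ids = set(sel.index) if sel is not None else set()
        found += sum(ps.set_id in ids for ps in planted)
    report["planted_sets"] = {"planted": planted_total, "selected": found}

    if enr_rows is not None:
        enr = pd.concat(enr_rows, ignore_index=True)
        hits = 0
        for pr in truth.planted_regulators:
            sub = enr[(enr["tissue"] == pr.tissue) & (enr["regulator_id"] == pr.regulator_id)]
            if len(sub) and float(sub["q"].iloc[0]) < 0.05:
                hits += 1
        report["planted_regulators"] = {"planted": len(truth.planted_regulators),
                                        "recovered_q_lt_0.05": hits}

    if modules is not None:
        block_stats = {}
        module_members = {m: set(sub.index) for m, sub in modules.groupby("module")
                          if m != coexpression.UNASSIGNED}
        for block_id, genes in truth.coexpr_blocks.items():
            gset = set(genes)
            jac = max((len(gset & mm) / len(gset | mm) for mm in module_members.values()),
                      default=0.0)
            # coverage: a block may sit inside a larger (correct) module of
            # co-responding genes, so also report the best containment
            cov = max((len(gset & mm) / len(gset) for mm in module_members.values()),
                      default=0.0)
            block_stats[block_id] = {"jaccard": round(jac, 4), "coverage": round(cov, 4)}
        report["coexpr_blocks"] = block_stats
    return report
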