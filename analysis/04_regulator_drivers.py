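#!/usr/bin/env python
"""Screen for TF / microRNA drivers of the diet response.

For each tissue, takes the member genes of the reporter-selected gene sets
as the responding list, tests every regulator's targets for
over-representation (one-sided Fisher, BH within regulator type), builds
the pairwise target co-occurrence matrix of the enriched regulators over
the downregulated responders, and tests each regulator's targets for a
collective downward fold-change shift (one-sided KS).
"""

import argparse
from pathlib import Path

import pandas as pd

from dietmap import differential as dd
from dietmap import io, regulation, reporter


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--p-cut", type=float, default=0.001)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    study = io.read_expression_study(args.datadir / "expression.tsv",
                                     args.datadir / "samples.tsv")
    study = study.with_expression(dd.quantile_normalize(study.expression))
    go_sets = io.read_gmt(args.datadir / "go_sets.gmt")
    reg_table = io.read_regulator_targets(args.datadir / "regulator_targets.tsv")
    universe = list(study.gene_ids)
    target_map = io.targets_by_regulator(reg_table, universe=universe)
    reg_types = dict(reg_table.drop_duplicates("regulator_id")
                     .set_index("regulator_id")["type"])

    enr_frames, ks_rows = [], []
    for i, tissue in enumerate(study.tissues):
        tab = dd.per_tissue_ttest(study, tissue)
        z = pd.Series(reporter.p_to_z(tab["p_value"]), index=tab.index)
        res = reporter.reporter_scores(z, go_sets, min_set_size=3,
                                       seed=args.seed * 100 + i,
                                       log2fc_by_gene=tab["log2fc"])
        sel = reporter.select_reporters(res, args.p_cut)
        members: set[str] = set()
        for fid in sel.index:
            members |= go_sets[fid] & set(universe)
        down = set(tab["log2fc"].reindex(sorted(members)).pipe(lambda s: s[s < 0]).index)

        enr = regulation.fisher_enrichment(members, universe, target_map, reg_types)
        enr.insert(0, "tissue", tissue)
        enr_frames.append(enr.reset_index())
        hits = sorted(enr.index[enr["q"] < 0.05])
        print(f"{tissue}: {len(members)} responding genes ({len(down)} down); "
              f"enriched regulators at q<0.05: {', '.join(hits) if hits else 'none'}")
        if hits:
            co = regulation.cooccurrence_matrix(hits, target_map, down)
            co.to_csv(args.outdir / f"cooccurrence_{tissue}.tsv", sep="\t")

        for reg in sorted(target_map):
            d, p = regulation.ks_target_shift(tab["log2fc"], target_map[reg],
                                              side="down", seed=args.seed)
            ks_rows.append((tissue, reg, reg_types.get(reg, "?"), d, p))

    pd.concat(enr_frames, ignore_index=True).to_csv(
        args.outdir / "regulator_enrichment.tsv", sep="\t", index=False)
    ks = pd.DataFrame(ks_rows, columns=["tissue", "regulator_id", "type", "D", "p"])
    ks.to_csv(args.outdir / "ks_targets.tsv", sep="\t", index=False)
    shifted = ks[ks["p"] < 0.05]
    print(f"KS target shift: {len(shifted)} regulator x tissue pairs with a "
          f"downward shift at p<0.05 (" +
          ", ".join(f"{r.regulator_id}@{r.tissue}" for r in shifted.itertuples()) + ")")


if __name__ == "__main__":
    main()
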