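#!/usr/bin/env python
"""Cross-tissue co-expression modules on the diet-responsive genes.

Selects genes by the ANOVA diet-factor Q-value, removes per-tissue offsets
(which otherwise dominate every correlation), builds the soft-thresholded
network and its topological overlap matrix, cuts the average-linkage tree
into modules, and tests each module for gene-set enrichment.
"""

import argparse
from pathlib import Path

import pandas as pd

from dietmap import coexpression as cx
from dietmap import io


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--q-cut", type=float, default=0.05)
    ap.add_argument("--beta", type=float, default=6.0)
    ap.add_argument("--cut-height", type=float, default=0.85)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    anova = pd.read_csv(args.outdir / "anova.tsv", sep="\t", index_col=0)
    study = io.read_expression_study(args.datadir / "expression.tsv",
                                     args.datadir / "samples.tsv")
    genes = cx.select_diet_genes(anova, args.q_cut)
    print(f"{len(genes)} diet-responsive genes at ANOVA diet Q < {args.q_cut}")

    expr = study.expression.loc[genes]
    for tissue in study.tissues:  # remove tissue offsets before correlating
        cols = study.samples_where(tissue=tissue)
        expr[cols] = expr[cols].sub(expr[cols].mean(axis=1), axis=0)

    adj = cx.adjacency(expr, beta=args.beta)
    tom_m = cx.tom(adj)
    tom_m.to_csv(args.outdir / "tom.tsv", sep="\t")
    modules = cx.detect_modules(tom_m, cut_height=args.cut_height)
    modules.to_csv(args.outdir / "modules.tsv", sep="\t")
    sizes = modules["module"].value_counts().to_dict()
    print(f"modules (beta={args.beta}, cut={args.cut_height}): {sizes}")

    go_sets = io.read_gmt(args.datadir / "go_sets.gmt")
    enr = cx.module_enrichment(modules, go_sets)
    enr.to_csv(args.outdir / "module_enrichment.tsv", sep="\t", index=False)
    hits = enr[enr["q"] < 0.05]
    for row in hits.itertuples():
        print(f"  {row.module}: enriched for {row.set_id} "
              f"(overlap {row.overlap}/{row.set_size}, q={row.q:.2e})")


if __name__ == "__main__":
    main()
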