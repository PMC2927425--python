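#!/usr/bin/env python
"""Simulate the three-tissue two-diet cohort and write the input bundle.

Generates the synthetic study the later steps analyze: a log2 expression
matrix for liver, skeletal muscle and white adipose tissue (2 diets x 3
replicate animals each), a gene-set collection with three planted
diet-responsive sets per tissue, a second unplanted collection, a toy
metabolic model and a regulator->target table with two planted regulators.
Writes everything under results/data/ plus the planted truth for later
comparison.
"""

import argparse
import json
from pathlib import Path

from dietmap import io
from dietmap.pipeline import demo_config
from dietmap.simulate import (generate_expression, generate_gene_sets,
                              generate_metabolic_model, generate_regulator_targets,
                              generate_secondary_gene_sets)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    cfg = demo_config("unused", seed=args.seed).simulation
    args.outdir.mkdir(parents=True, exist_ok=True)

    study, truth = generate_expression(cfg)
    io.write_expression_study(study, args.outdir / "expression.tsv",
                              args.outdir / "samples.tsv", args.outdir / "genes.tsv")
    go_sets, _ = generate_gene_sets(cfg)
    io.write_gmt(go_sets, args.outdir / "go_sets.gmt")
    io.write_gmt(generate_secondary_gene_sets(cfg), args.outdir / "reactome_sets.gmt")
    _, triples = generate_metabolic_model(cfg)
    io.write_model_triples(triples, args.outdir / "model_triples.tsv")
    reg_table, _ = generate_regulator_targets(cfg)
    io.write_regulator_targets(reg_table, args.outdir / "regulator_targets.tsv")

    truth_obj = {
        "planted_sets": {t: [{"set_id": ps.set_id, "direction": ps.direction,
                              "size": len(ps.members)} for ps in planted]
                         for t, planted in truth.planted_sets.items()},
        "planted_regulators": [{"regulator_id": pr.regulator_id, "type": pr.reg_type,
                                "tissue": pr.tissue} for pr in truth.planted_regulators],
        "coexpr_blocks": {b: sorted(g) for b, g in truth.coexpr_blocks.items()},
    }
    (args.outdir / "truth.json").write_text(json.dumps(truth_obj, indent=2, sort_keys=True))

    print(f"cohort: {study.expression.shape[0]} genes x {study.expression.shape[1]} samples "
          f"({', '.join(study.tissues)}; groups {', '.join(study.groups)})")
    for tissue, planted in truth.planted_sets.items():
        print(f"  planted in {tissue}: " + ", ".join(
            f"{ps.set_id}({ps.direction},{len(ps.members)})" for ps in planted))
    print(f"  planted regulators: " + ", ".join(
        f"{pr.regulator_id}({pr.reg_type},{pr.tissue})" for pr in truth.planted_regulators))
    print(f"wrote input bundle to {args.outdir}")


if __name__ == "__main__":
    main()
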