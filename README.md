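# dietmap

Integrative analysis of multi-tissue transcriptome studies of diet: given a
log2 expression matrix over several tissues and two diet groups, `dietmap`
runs the full chain from per-gene statistics to network-level biology —
differential tests, reporter-feature scoring over gene-set and metabolic
networks, transcription-factor / microRNA driver screens, and
topological-overlap co-expression modules. It is aimed at the common
nutrigenomics design where a handful of animals per diet group are profiled
in a few metabolically important tissues (liver, skeletal muscle, adipose),
the tissue effect dwarfs the diet effect, and the diet signal is *diffuse*:
many genes in a pathway shift a little, few pass a per-gene significance
cut.

A first-class synthetic-data generator emulates exactly that design (3
tissues x 2 diets x 3 replicates) and plants known pathway, regulator and
co-expression signals, so every stage of the pipeline is validated against
ground truth.

## The statistics at the core

**Reporter features.** Per-gene p-values (from the within-tissue diet
t-test) are transformed with the inverse normal, z_g = Φ⁻¹(1 − p_g). A
feature F — a gene-set term, or a metabolite with its neighboring enzyme
genes in a metabolic model — with k member genes scores

    Z_raw(F) = Σ_{g∈F} z_g / √k
    Z_corr(F) = (Z_raw(F) − μ_k) / σ_k,      p(F) = 1 − Φ(Z_corr(F))

where μ_k, σ_k are estimated from 10⁴ random k-subsets of the gene
universe. The background correction makes features of different sizes
comparable and keeps the null distribution uniform regardless of the shape
of the study's p-value spectrum. Because the score uses *all* member
p-values rather than a significant/not dichotomy, it retains power in the
diffuse-signal regime where the classical hypergeometric test (also
provided, as the baseline) sees nothing.

**Metabolite neighborhoods.** A genome-scale metabolic model reduced to
gene–reaction–metabolite triples maps each metabolite to the genes of every
reaction touching it; metabolites above a reaction-degree cut (currency
cofactors: ATP, water, …) are filtered out.

**Regulator drivers.** One-sided Fisher exact tests of target
over-representation among responding genes (BH-corrected within TF and
miRNA families separately), pairwise target co-occurrence counts, and a
one-sided two-sample Kolmogorov–Smirnov test for a collective downward
shift of a regulator's targets' log2 fold-changes.

**Co-expression modules.** On the ANOVA diet-responsive gene list:
soft-thresholded adjacency a_ij = |cor(x_i,x_j)|^β (β = 6), topological
overlap TOM_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij), average-linkage
clustering of 1 − TOM with a static height cut, and per-module gene-set
enrichment.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
cohort (they are thin drivers over the library; every computation lives in
`src/dietmap/`):

```
python analysis/01_simulate_cohort.py --seed 0
python analysis/02_differential_expression.py
python analysis/03_reporter_features.py
python analysis/04_regulator_drivers.py
python analysis/05_coexpression_modules.py
```

Step 01 plants three diet-responsive gene sets per tissue (e.g. liver:
`SET0001(down,40), SET0002(up,48), SET0003(down,50)`), a TF whose targets
are enriched among liver's downregulated genes and a miRNA likewise in
muscle, and two 30-gene co-expression blocks. The later steps print, with
seed 0:

```
SVD: PC1 carries 48.6% of variance; per-tissue PC1 spans
  {'liver': (47.9, 48.3), 'muscle': (-74.0, -72.9), 'wat': (24.8, 26.4)}
t-test liver: 120 genes at Q < 0.05
ANOVA: 387 diet-responsive ... genes at Q < 0.05
reporter[go] liver: 5 features at p < 0.001 - top: SET0003(down), SET0002(up), SET0001(down), ...
liver: 138 responding genes (90 down); enriched regulators at q<0.05: TF001
KS target shift: ... TF001@liver, MIR001@muscle ...
modules (beta=6.0, cut=0.85): {'M1': 132, 'M2': 130, 'M3': 119, 'unassigned': 6}
  M1: enriched for SET0001 (overlap 38/38, q=5.42e-19)
```

Reading the output: the SVD confirms that tissue identity, not diet,
separates the samples (the per-tissue PC1 ranges do not overlap, and the
two diets mix within each range). The reporter stage ranks every planted
set at the top of its own tissue at p < 0.001 while the unplanted
"Reactome-role" and metabolite networks yield no selections — the expected
negative control. The regulator screen recovers exactly the two planted
drivers, and the co-expression stage partitions the diet-responsive genes
into three modules that coincide with the per-tissue planted programs, each
confirmed by module enrichment.

The same pipeline runs on real files (expression/metadata/annotation TSVs,
GMT collections, model triples, regulator tables — formats documented in
`src/dietmap/io.py`) through the CLI:

```
dietmap demo --outdir demo_run --seed 0        # one-command synthetic demo
dietmap simulate --outdir bundle --seed 0      # write an input bundle
dietmap validate --expression ... --metadata ...   # schema checks
dietmap run --config config.yaml               # full pipeline from YAML
```

Every run writes a `manifest.json` with parameters, per-stage seeds and
sha256 checksums of all outputs; reruns under the same seed are
byte-identical.

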