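# Methods

This note documents the models, defaults and design choices behind
`dietmap`, and what the synthetic validation does and does not establish.

## The synthetic cohort

The generator emulates a two-diet feeding study profiled in three tissues
(liver, skeletal muscle, white adipose tissue) with three replicate animals
per tissue × diet cell — 18 arrays in one batch. Log2 expression of gene
*g* in sample *(t, d, r)* is

    x = baseline_g + τ_{g,t} + δ_{g,t}·1[d = herring] + e_{g,s}

- `baseline_g ~ N(7, 1)` log2 units, a typical array intensity scale.
- `τ_{g,t} ~ N(0, tissue_effect_sd²)`, default sd 2.0 log2 units: tissue
  identity dominates every global view of the data, as it does in real
  multi-tissue designs.
- `δ_{g,t} = ±diet_effect_size` (default 0.5 log2) only for genes in the
  planted sets of tissue *t*, sign per set. 0.5 log2 (×1.4) with
  replicate noise sd 0.3 puts individual genes near t-test powerlessness
  at n = 3 vs 3 (p ≈ 0.1) — the diffuse regime the aggregation statistic
  exists for.
- Noise: `e ~ N(0, 0.3²)` per replicate. For genes in a co-expression
  block the same variance is *decomposed* into a shared and a private
  part, `e = 0.3·(√ρ·f_{b,s} + √(1−ρ)·ε)`, with one latent factor `f` per
  block and sample and ρ = `block_correlation` (default 0.8). Decomposing
  rather than adding keeps a block gene's marginal noise identical to any
  other gene's, so block membership does not distort differential tests.
  The factor is standardized to empirical mean 0 / sd 1 across the 18
  samples: with so few samples the realized variance of an unstandardized
  factor occasionally collapses (observed as low as 0.36), in which case
  the dataset simply would not contain the correlation structure the
  configuration promises. Standardization makes the planted correlation a
  per-dataset guarantee.

Planted gene sets are carved from disjoint chunks of the gene pool (no
gene receives two conflicting shifts); remaining sets are sampled freely
with overlap. Set sizes default to 20–100 members, matching the size range
of the gene-set terms such designs actually report (tens to a few hundred
members); far smaller sets would sit below any aggregation statistic's
power at a 0.5-log2 effect and have no real counterpart. Each
co-expression block is mirrored by a gene set (`SET_BLOCK_*`) so module
enrichment has a recoverable truth. One collection carries the planted
signal (GO role); a second, unplanted collection (Reactome role) acts as a
negative control.

Regulator→target tables are Bernoulli per (regulator, gene) at rate 0.05 —
the order of a realistic per-regulator target fraction (conserved miRNA or
TF target sets are a few percent of the genome) — while planted regulators
target the *down*-shifted genes of a designated tissue at rate 0.6, giving
both a recoverable Fisher enrichment and a detectable downward
fold-change shift. The toy metabolic model draws 1–3 genes and 2–4
metabolites per reaction plus two "currency" metabolites attached to ~70%
of all reactions, to exercise the degree filter.

Gene annotation assigns chromosomes 1–19 and X with probability
proportional to mouse-like chromosome lengths and uniform positions; only
the ordering matters for the genome-ordered export.

Everything is a pure function of the config including its seed; separate
RNG streams per artifact make each generator independently reproducible.

**What the synthetic data does not contain:** probe-level noise and
normalization artifacts, correlated baseline structure (housekeeping
programs), batch effects, non-normal heavy-tailed noise, overlapping and
hierarchical ontology terms, or realistic metabolic network topology.
Passing tests therefore demonstrate correctness of the statistics and
recoverability of signals of the stated magnitude under clean Gaussian
conditions — not performance on any particular real dataset.

## Differential stage

- Quantile normalization maps every sample to the common distribution of
  row-wise means of the column-sorted matrix; ties receive interpolated
  reference values (so tied inputs stay tied) and the transform is
  idempotent.
- SVD is computed on row-centered (not scaled) data, so component variance
  fractions decompose expression variance.
- The diet test within a tissue is the classical equal-variance two-sample
  t (df = n₁+n₂−2); Welch is available behind a flag. log2 fold-change is
  herring − beef (second group minus first).
- The two-way ANOVA is the balanced fixed-effects cell-means decomposition
  with interaction; balance is asserted, under which type I/II/III sums of
  squares coincide.
- Multiple testing uses Benjamini–Hochberg throughout ("Q-values");
  deterministic and oracle-checkable. p-values are clamped at 1e-16 before
  any log or inverse-normal transform.
- The genome-ordered export uses 0-based, half-open length-1 intervals,
  chromosomes ordered 1..19 then X.
- Sample clustering itself is out of scope; the pipeline exports the
  sample x sample distance matrix (euclidean or 1 - correlation, over
  the significant-gene union) as the plot-ready input for heatmaps.

## Reporter stage

Defaults: n_bg = 10 000 background subsets per distinct member count,
min_set_size 3 for gene-set collections and 2 for metabolite
neighborhoods, currency filter at > 50 reactions. Background subsets are
drawn *without* replacement via a vectorized partial-permutation trick:
one shuffle per background draw yields a uniform k-subset simultaneously
for every k, so all set sizes share a single RNG stream. μ_k and σ_k are
cached per k within a call.

The gene-level input is the per-tissue t-test p-value (two-sided, so
coherently down- and up-shifted sets both score; Q-values can be supplied
instead). A feature's direction label is the sign of its members' mean
log2 fold-change — a display aid, not part of the statistic. Degenerate
universes (zero background spread) raise instead of returning fake
scores.

X-scores standardize each gene row to mean 0 / sd 1 across all samples and
average standardized values over member genes × group samples (6 tissue ×
diet groups, or 3 tissue groups); with equal group sizes each feature's
X-scores average to zero by construction, so the heatmap reads as
departures from the study grand mean.

## Regulator stage

The responding gene list fed to the Fisher screen is the union of member
genes of the reporter-selected sets per tissue (falling back to the
per-gene Q < 0.05 list when nothing is selected); the co-occurrence scope
is its downregulated subset. One-sided (over-representation) Fisher exact
p equals the hypergeometric upper tail; odds ratios use Haldane 0.5
correction on zero cells; BH is applied within regulator type, since TF
and miRNA screens answer separate questions. The KS shift test is
one-sided ("targets stochastically smaller" for repressors), asymptotic
for group sizes ≥ 5 and an exact seeded permutation below that.

## Co-expression stage

Gene selection: ANOVA diet-factor Q < 0.05; the pipeline falls back to the
top 150 genes by diet p when fewer than twice the minimum module size
pass, so the stage always produces a diagnosable result. Tissue offsets
are removed (within-tissue centering) before correlating — with three
tissue means per gene dominating the raw profiles, cross-tissue
correlations would otherwise reflect tissue identity, not diet-driven
covariation; the option can be disabled.

Network defaults: unsigned Pearson adjacency, β = 6 (a scale-free-fit
chooser `scale_free_beta` is available), TOM with diagonal 1 and the
isolated-pair 0/0 case defined as 0, average-linkage clustering of
1 − TOM on a canonical (sorted-gene) ordering so the partition is
permutation-invariant, static cut, min_module_size 10, modules labeled by
decreasing size.

The static cut height defaults to **0.85**. At this package's validation
scale (30-gene blocks at ρ = 0.8 among 60 unstructured genes, 18 samples)
a 0.95 cut systematically absorbs noise genes that chance-correlate with a
block's latent factor (recovery rate ~0.2), while 0.85 recovers both
blocks at Jaccard ≥ 0.9 in ≥ 95% of runs and degrades monotonically as the
planted correlation weakens. Heights near 0.9–0.95 only make sense with
many more samples, where correlation estimates are tight. Dynamic tree
cutting would adapt per branch but is deliberately out of scope; the
static cut keeps the procedure deterministic and transparent.

## Pipeline and reproducibility

Each stage writes a TSV; a manifest records package version, full
parameters and sha256 checksums of every output. All randomness flows
through named per-stage seeds derived from one master seed by hashing, so
stage results are independently reproducible and reruns are
byte-identical. Stage failures raise a typed error carrying the stage name
and a machine-readable code; earlier outputs are retained.

Validation studies (`dietmap.benchmarks`) use deliberately desk-scale
problem sizes — 2000-gene universes, 2000 null features, 20-run recovery
studies, 100-run regulator studies — chosen so the whole battery completes
in a few minutes on one CPU while keeping Monte-Carlo error on the
reported rates around or below the margins being asserted.

## Known limitations

- The equal-variance t at n = 3 vs 3 is noisy; no variance moderation
  (empirical-Bayes shrinkage) is applied, by design fidelity to the
  classical analysis chain.
- The reporter background treats genes as exchangeable; gene–gene
  correlation within real pathways makes the background slightly
  anti-conservative in principle (the null-calibration study bounds this
  under independence only).
- The static tree cut has one global height; strongly nested module
  structure would need dynamic cutting.
- The hypergeometric baseline, Fisher screens and module enrichment all
  condition on hard gene lists; their power depends entirely on the
  upstream cut.
- Storey-type Q-values are not implemented; BH is the only FDR method.
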