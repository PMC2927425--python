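"""Synthetic multi-tissue diet-study generator with planted structure.

Emulates the design of a two-diet mouse feeding study profiled in three
metabolically important tissues (liver, skeletal muscle, white adipose
tissue), two diet groups and three replicate animals per tissue x group
cell.  The generator plants three kinds of recoverable signal so every
downstream stage of the pipeline has a known truth to be checked against:

* **pathway signal** — a handful of gene sets per tissue whose members
  receive a coherent diet shift (up or down) of ``diet_effect_size`` log2
  units in that tissue only;
* **regulator signal** — regulators whose targets are enriched among the
  diet-shifted genes of a designated tissue, so target over-representation
  and target fold-change shifts are detectable;
* **co-expression signal** — gene blocks sharing a latent factor that
  induces a chosen pairwise correlation, recoverable as network modules.

The model for the log2 expression of gene *g* in sample *(t, d, r)* is

    x = baseline_g + tau_{g,t} + delta_{g,t} * [d = second group] + e_{g,s}

with ``tau ~ N(0, tissue_effect_sd^2)`` per gene x tissue (tissue identity
dominates when ``tissue_effect_sd`` is large, mirroring the real situation
where tissue differences dwarf diet differences), ``delta`` the planted
diet effect, and ``e`` the replicate-level noise.  For an ordinary gene
``e = eps_{g,s} ~ N(0, noise_sd^2)``; for a gene in co-expression block b
the same noise variance is *decomposed* into a shared and a private part,

    e = noise_sd * (sqrt(rho) * f_{b,s} + sqrt(1 - rho) * eps_{g,s}),

with ``f`` a standard-normal latent factor per block and sample and
``rho = block_correlation``.  The expected pairwise Pearson correlation
within a block is exactly rho (net of tissue and diet offsets) while the
marginal noise variance stays ``noise_sd^2``, so block membership does not
change a gene's differential-test behavior.

Everything is a pure function of the :class:`SimulationConfig` (including
its seed): the same config reproduces every artifact bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .networks import FeatureNetwork
from .study import CHROMOSOME_ORDER, ExpressionStudy

__all__ = [
    "SimulationConfig", "SyntheticTruth", "PlantedSet", "PlantedRegulator",
    "generate_expression", "generate_gene_sets", "generate_metabolic_model",
    "generate_regulator_targets",
]

# distinct RNG streams per artifact so each generator op is independently
# deterministic under the same config
_STREAM_SETS = 1
_STREAM_EXPR = 2
_STREAM_ANNOT = 3
_STREAM_MODEL = 4
_STREAM_REGS = 5
_STREAM_SETS2 = 6


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study; the seed fully determines output."""

    n_genes: int = 2000
    tissues: tuple[str, ...] = ("liver", "muscle", "wat")
    groups: tuple[str, ...] = ("beef", "herring")  # second group carries the diet shift
    replicates_per_cell: int = 3

    baseline_mean: float = 7.0        # log2 units, typical array intensity
    baseline_sd: float = 1.0
    tissue_effect_sd: float = 2.0     # log2 units; dominates the diet effect
    diet_effect_size: float = 0.5     # log2 units added to planted genes
    noise_sd: float = 0.3             # replicate-level log2 noise

    n_gene_sets: int = 50
    set_size_range: tuple[int, int] = (20, 100)
    n_planted_sets_per_tissue: int = 3
    planted_directions: tuple[str, ...] = ("down", "up", "down")  # cycled per tissue
    n_gene_sets_secondary: int = 30   # second, unplanted collection (Reactome role)

    n_regulators: int = 20
    regulator_target_rate: float = 0.05
    n_planted_regulators: int = 2
    planted_regulator_target_rate: float = 0.6

    n_coexpr_blocks: int = 2
    block_size: int = 30
    block_correlation: float = 0.8
    allow_overlap: bool = False       # blocks vs planted sets share gene pool if True
    blocks_from_planted: bool = False  # carve block b out of planted set b instead

    n_reactions: int = 150
    n_metabolites: int = 80
    genes_per_reaction: tuple[int, int] = (1, 3)
    metabolites_per_reaction: tuple[int, int] = (2, 4)
    n_currency_metabolites: int = 2
    currency_attachment: float = 0.7  # fraction of reactions a currency metabolite joins

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "replicates_per_cell", "n_gene_sets", "n_regulators",
                     "n_coexpr_blocks", "block_size", "n_reactions", "n_metabolites"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.block_correlation < 1.0:
            raise ValueError("block_correlation must lie in (0, 1)")
        if len(self.groups) != 2:
            raise ValueError("exactly two diet groups are supported")
        lo, hi = self.set_size_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid set_size_range")
        if hi > self.n_genes:
            raise ValueError("set sizes exceed n_genes")
        if any(d not in ("up", "down") for d in self.planted_directions):
            raise ValueError("planted_directions entries must be 'up' or 'down'")
        if self.n_planted_sets_per_tissue * len(self.tissues) > self.n_gene_sets:
            raise ValueError("more planted sets than gene sets")
        if self.blocks_from_planted and \
                self.n_coexpr_blocks > self.n_planted_sets_per_tissue * len(self.tissues):
            raise ValueError("more co-expression blocks than planted sets to carve them from")
        n_block_genes = 0 if (self.allow_overlap or self.blocks_from_planted) \
            else self.n_coexpr_blocks * self.block_size
        need = n_block_genes + self.n_planted_sets_per_tissue * len(self.tissues) * hi
        if need > self.n_genes:
            raise ValueError(
                f"gene pool too small: {self.n_genes} genes cannot host "
                f"{n_block_genes} block genes plus disjoint planted sets of size up to {hi}"
            )
        if not 0.0 <= self.regulator_target_rate <= 1.0:
            raise ValueError("regulator_target_rate must lie in [0, 1]")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class PlantedSet:
    set_id: str
    tissue: str
    direction: str            # "up" or "down" in the second diet group
    effect_size: float        # log2 units
    members: frozenset[str]


@dataclass(frozen=True)
class PlantedRegulator:
    regulator_id: str
    reg_type: str             # "TF" or "miRNA"
    tissue: str               # tissue whose shifted genes are enriched targets
    direction: str            # direction of the shifted genes it targets


@dataclass
class SyntheticTruth:
    """Ground truth of the planted signals, keyed for acceptance checks."""

    planted_sets: dict[str, list[PlantedSet]] = field(default_factory=dict)
    planted_regulators: list[PlantedRegulator] = field(default_factory=list)
    coexpr_blocks: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def perturbed_genes(self, tissue: str, direction: str | None = None) -> frozenset[str]:
        """Genes carrying a planted diet shift in ``tissue`` (optionally one direction)."""
        out: set[str] = set()
        for ps in self.planted_sets.get(tissue, []):
            if direction is None or ps.direction == direction:
                out |= ps.members
        return frozenset(out)


def _gene_ids(config: SimulationConfig) -> list[str]:
    return [f"G{i:05d}" for i in range(config.n_genes)]


def _block_assignment(config: SimulationConfig) -> dict[str, tuple[str, ...]]:
    """Co-expression blocks occupy the leading genes (deterministic chunks)."""
    genes = _gene_ids(config)
    blocks = {}
    for b in range(config.n_coexpr_blocks):
        blocks[f"B{b + 1}"] = tuple(genes[b * config.block_size:(b + 1) * config.block_size])
    return blocks


# -- gene sets ----------------------------------------------------------------

def generate_gene_sets(config: SimulationConfig) -> tuple[FeatureNetwork, SyntheticTruth]:
    """Primary gene-set collection (GO role) with planted, membership-disjoint sets.

    The planted sets for all tissues are carved from disjoint chunks of the
    non-block gene pool (so a gene never receives conflicting diet shifts);
    the remaining sets are sampled freely, overlap allowed.  One extra set
    per co-expression block (named ``SET_BLOCK_<id>``) mirrors each block's
    membership so module-level enrichment has a recoverable truth.
    """
    rng = np.random.default_rng([config.seed, _STREAM_SETS])
    genes = np.array(_gene_ids(config))
    if config.blocks_from_planted:
        blocks = {}
        block_genes: set[str] = set()
    else:
        blocks = _block_assignment(config)
        block_genes = set() if config.allow_overlap else {g for gs in blocks.values() for g in gs}
    pool = np.array([g for g in genes if g not in block_genes])

    lo, hi = config.set_size_range
    n_planted = config.n_planted_sets_per_tissue * len(config.tissues)
    sizes = rng.integers(lo, hi + 1, size=config.n_gene_sets)

    shuffled = rng.permutation(pool)
    features: dict[str, frozenset[str]] = {}
    truth = SyntheticTruth(coexpr_blocks=blocks)
    cursor = 0
    idx = 0
    for t, tissue in enumerate(config.tissues):
        truth.planted_sets[tissue] = []
        for j in range(config.n_planted_sets_per_tissue):
            size = int(sizes[idx])
            members = frozenset(shuffled[cursor:cursor + size])
            cursor += size
            name = f"SET{idx + 1:04d}"
            direction = config.planted_directions[j % len(config.planted_directions)]
            features[name] = members
            truth.planted_sets[tissue].append(
                PlantedSet(name, tissue, direction, config.diet_effect_size, members)
            )
            idx += 1
    for idx in range(n_planted, config.n_gene_sets):
        size = int(sizes[idx])
        features[f"SET{idx + 1:04d}"] = frozenset(rng.choice(pool, size=size, replace=False))
    if config.blocks_from_planted:
        planted_flat = [ps for tissue in config.tissues for ps in truth.planted_sets[tissue]]
        for b in range(config.n_coexpr_blocks):
            members = sorted(planted_flat[b].members)[:config.block_size]
            blocks[f"B{b + 1}"] = tuple(members)
        truth.coexpr_blocks = blocks
    for block_id, block_members in blocks.items():
        features[f"SET_BLOCK_{block_id}"] = frozenset(block_members)
    return FeatureNetwork(features, kind="gene_set_collection", provenance="synthetic-go"), truth


def generate_secondary_gene_sets(config: SimulationConfig) -> FeatureNetwork:
    """Second, unplanted collection (Reactome role): random sets over all genes."""
    rng = np.random.default_rng([config.seed, _STREAM_SETS2])
    genes = np.array(_gene_ids(config))
    lo, hi = config.set_size_range
    features = {}
    for i in range(config.n_gene_sets_secondary):
        size = int(rng.integers(lo, hi + 1))
        features[f"RSET{i + 1:04d}"] = frozenset(rng.choice(genes, size=size, replace=False))
    return FeatureNetwork(features, kind="gene_set_collection", provenance="synthetic-reactome")


# -- expression ---------------------------------------------------------------

# mouse-like karyotype: autosome lengths decrease with rank, X is large
_CHROM_LENGTH_BP = {
    **{str(i): int((200 - 7 * (i - 1)) * 1e6) for i in range(1, 20)},
    "X": int(171e6),
}


def _annotation(config: SimulationConfig) -> pd.DataFrame:
    rng = np.random.default_rng([config.seed, _STREAM_ANNOT])
    chroms = np.array(CHROMOSOME_ORDER)
    lengths = np.array([_CHROM_LENGTH_BP[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    chosen = rng.choice(chroms, size=config.n_genes, p=probs)
    pos = np.array([rng.integers(0, _CHROM_LENGTH_BP[c]) for c in chosen])
    return pd.DataFrame(
        {"chromosome": chosen, "position_bp": pos},
        index=pd.Index(_gene_ids(config), name="gene_id"),
    )


def generate_expression(config: SimulationConfig) -> tuple[ExpressionStudy, SyntheticTruth]:
    """Simulate the log2 expression matrix with all planted signals.

    Returns the study (matrix + sample metadata + gene annotation) and the
    planted-signal truth (including regulator truth, so one call yields the
    complete ground-truth record).
    """
    _, truth = generate_gene_sets(config)
    _, reg_truth = generate_regulator_targets(config)
    truth.planted_regulators = reg_truth.planted_regulators

    rng = np.random.default_rng([config.seed, _STREAM_EXPR])
    genes = _gene_ids(config)
    n_genes = config.n_genes
    tissues, groups = config.tissues, config.groups
    reps = config.replicates_per_cell

    sample_rows = []
    for tissue in tissues:
        for group in groups:
            for r in range(1, reps + 1):
                sample_rows.append((f"{tissue}_{group}_r{r}", tissue, group, r))
    sample_ids = [s[0] for s in sample_rows]
    meta = pd.DataFrame(sample_rows, columns=["sample_id", "tissue", "group", "replicate"]
                        ).set_index("sample_id")
    n_samples = len(sample_ids)

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n_genes)
    tau = rng.normal(0.0, config.tissue_effect_sd, size=(n_genes, len(tissues)))

    gene_index = {g: i for i, g in enumerate(genes)}
    delta = np.zeros((n_genes, len(tissues)))
    for t, tissue in enumerate(tissues):
        for ps in truth.planted_sets.get(tissue, []):
            sign = 1.0 if ps.direction == "up" else -1.0
            for g in ps.members:
                delta[gene_index[g], t] = sign * ps.effect_size

    rho = config.block_correlation
    factors = rng.normal(0.0, 1.0, size=(config.n_coexpr_blocks, n_samples))
    # standardize each factor across samples so the planted within-block
    # correlation holds in every realized dataset, not merely in expectation
    factors = (factors - factors.mean(axis=1, keepdims=True)) \
        / factors.std(axis=1, ddof=0, keepdims=True)
    noise = rng.normal(0.0, config.noise_sd, size=(n_genes, n_samples))

    values = np.empty((n_genes, n_samples))
    for s, (sid, tissue, group, _r) in enumerate(sample_rows):
        t = tissues.index(tissue)
        shift = delta[:, t] if group == groups[1] else 0.0
        values[:, s] = baseline + tau[:, t] + shift + noise[:, s]
    # shared/private noise decomposition for block genes (marginal variance kept)
    for b, (block_id, block_members) in enumerate(truth.coexpr_blocks.items()):
        rows = [gene_index[g] for g in block_members]
        values[rows, :] += (np.sqrt(1.0 - rho) - 1.0) * noise[rows, :] \
            + config.noise_sd * np.sqrt(rho) * factors[b][None, :]

    expr = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=sample_ids)
    study = ExpressionStudy(expr, meta, _annotation(config))
    return study, truth


# -- metabolic model ----------------------------------------------------------

def generate_metabolic_model(config: SimulationConfig) -> tuple[FeatureNetwork, pd.DataFrame]:
    """Random gene-reaction-metabolite associations in triple form.

    A configurable number of high-degree "currency-like" metabolites (ATP /
    water role) attach to most reactions so the reaction-degree filter of
    the metabolite scoring stage has something to remove.  The returned
    network maps each metabolite to the union of genes attached to any of
    its reactions (the unfiltered neighborhoods).
    """
    rng = np.random.default_rng([config.seed, _STREAM_MODEL])
    genes = np.array(_gene_ids(config))
    rxns = [f"R{i + 1:04d}" for i in range(config.n_reactions)]
    n_ordinary = config.n_metabolites - config.n_currency_metabolites
    if n_ordinary <= 0:
        raise ValueError("n_metabolites must exceed n_currency_metabolites")
    mets = [f"M{i + 1:04d}" for i in range(n_ordinary)]
    currency = [f"CUR{i + 1:02d}" for i in range(config.n_currency_metabolites)]

    glo, ghi = config.genes_per_reaction
    mlo, mhi = config.metabolites_per_reaction
    rows: list[tuple[str, str, str]] = []
    rxn_genes: dict[str, np.ndarray] = {}
    rxn_mets: dict[str, list[str]] = {}
    for rxn in rxns:
        gs = rng.choice(genes, size=int(rng.integers(glo, ghi + 1)), replace=False)
        ms = list(rng.choice(mets, size=int(rng.integers(mlo, mhi + 1)), replace=False))
        for cur in currency:
            if rng.random() < config.currency_attachment:
                ms.append(cur)
        rxn_genes[rxn], rxn_mets[rxn] = gs, ms
        rows.extend((rxn, g, "") for g in gs)
        rows.extend((rxn, "", m) for m in ms)

    triples = pd.DataFrame(rows, columns=["reaction_id", "gene_id", "metabolite_id"])
    neighbors: dict[str, set[str]] = {}
    for rxn in rxns:
        for m in rxn_mets[rxn]:
            neighbors.setdefault(m, set()).update(rxn_genes[rxn])
    network = FeatureNetwork(
        {m: frozenset(gs) for m, gs in neighbors.items()},
        kind="metabolite_bipartite", provenance="synthetic-gsmm",
    )
    return network, triples


# -- regulator targets --------------------------------------------------------

def generate_regulator_targets(config: SimulationConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Regulator->target long table with planted enriched regulators.

    Background membership is Bernoulli(``regulator_target_rate``) per
    (regulator, gene).  Planted regulators instead target the *down*-shifted
    genes of their designated tissue at ``planted_regulator_target_rate``,
    so both target over-representation and a downward target fold-change
    shift are recoverable.  Planted regulators alternate TF / miRNA and
    cycle through the tissues.
    """
    _, truth = generate_gene_sets(config)
    rng = np.random.default_rng([config.seed, _STREAM_REGS])
    genes = np.array(_gene_ids(config))

    n_tf = config.n_regulators // 2
    regulators = [(f"TF{i + 1:03d}", "TF") for i in range(n_tf)]
    regulators += [(f"MIR{i + 1:03d}", "miRNA") for i in range(config.n_regulators - n_tf)]

    planted: list[PlantedRegulator] = []
    planted_ids: dict[str, PlantedRegulator] = {}
    for j in range(config.n_planted_regulators):
        # alternate types: even -> TF slot j//2, odd -> miRNA slot j//2
        if j % 2 == 0 and j // 2 < n_tf:
            reg_id, reg_type = regulators[j // 2]
        else:
            reg_id, reg_type = regulators[n_tf + j // 2]
        tissue = config.tissues[j % len(config.tissues)]
        pr = PlantedRegulator(reg_id, reg_type, tissue, "down")
        planted.append(pr)
        planted_ids[reg_id] = pr

    rows: list[tuple[str, str, str]] = []
    for reg_id, reg_type in regulators:
        rates = np.full(config.n_genes, config.regulator_target_rate)
        if reg_id in planted_ids:
            pr = planted_ids[reg_id]
            hot = truth.perturbed_genes(pr.tissue, pr.direction)
            hot_idx = [i for i, g in enumerate(genes) if g in hot]
            rates[hot_idx] = config.planted_regulator_target_rate
        hit = rng.random(config.n_genes) < rates
        rows.extend((reg_id, g, reg_type) for g in genes[hit])

    table = pd.DataFrame(rows, columns=["regulator_id", "gene_id", "type"])
    truth.planted_regulators = planted
    return table, truth
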