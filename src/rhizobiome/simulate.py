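"""Synthetic rhizosphere-microbiome data with known ground truth.

The study design being emulated: a collection of potato cultivars grown in
replicate (51 cultivars × 3 replicates in the full design), each sample an
ASV count table over a shared phylogeny, with cultivars falling into latent
growth-performance clusters and communities assembled under one of five
ecological regimes (selection, dispersal, drift).

No generative model exists for the original data, so this module adopts the
minimal model under which phylogenetic null-model inference (βNTI) is
informative: taxa carry a Brownian-motion niche optimum evolved on the tree,
and a sample's taxon weights are the metacommunity abundances multiplied by
a Gaussian environmental filter centred on the sample's environment value.
Counts are multinomial at a fixed sequencing depth.

Every simulator is deterministic for a fixed seed; all randomness flows from
a single ``numpy.random.SeedSequence`` split into named child streams, so
e.g. widening the selection filter does not perturb the multinomial stream.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import FeatureTable

__all__ = [
    "AssemblyRegime",
    "SimulatedDataset",
    "simulate_phylogeny",
    "simulate_trait_optima",
    "simulate_community",
    "simulate_growth_traits",
    "simulate_taxonomy",
    "simulate_dataset",
    "REGIME_NAMES",
    "TRAIT_COLUMNS",
    "DEFAULT_CLUSTER_MEANS",
]

REGIME_NAMES = (
    "neutral",
    "homogeneous_selection",
    "heterogeneous_selection",
    "homogenizing_dispersal",
    "dispersal_limitation",
)

TRAIT_COLUMNS = [
    "shoot_fresh_weight",
    "shoot_dry_weight",
    "leaf_count",
    "tuber_weight",
    "tuber_number",
]

# Pot-scale 42-day greenhouse means for high / medium / low performance
# (grams for weights, counts for leaves and tubers).
DEFAULT_CLUSTER_MEANS = np.array(
    [
        [45.0, 6.0, 25.0, 30.0, 8.0],  # high
        [30.0, 4.0, 18.0, 18.0, 5.0],  # medium
        [18.0, 2.5, 12.0, 8.0, 3.0],  # low
    ]
)


@dataclass
class AssemblyRegime:
    """Parameters of one community-assembly scenario.

    Attributes
    ----------
    name:
        One of :data:`REGIME_NAMES`.
    selection_sd:
        Width σ of the Gaussian environmental filter applied to niche
        optima (same units as the optima). Small values mean strong
        selection; ∞ removes selection entirely.
    env_values:
        Environment value(s): a scalar shared by all samples
        (homogeneous selection) or one per sample (heterogeneous
        selection). ``None`` lets the simulator draw defaults.
    dispersal_mix:
        Fraction of every sample's reads drawn from a single shared
        community realisation (homogenizing dispersal; organisms mixing
        freely between samples).
    pool_overlap:
        Fraction of each island pool drawn from a common shared pool
        (dispersal limitation); 0 gives fully disjoint pools.
    recruitment:
        Fraction of the available taxon pool each sample recruits before
        multinomial sampling (ecological drift: random establishment
        failures).  At 1.0 every weighted taxon is available to every
        sample, which removes between-sample taxon turnover and with it
        the information the phylogenetic null model relies on.
    drift_sd:
        Sigma of a per-sample, per-taxon lognormal multiplier on the
        sampling weights (ecological drift: random proliferation and
        death).  Without it, narrow selection filters make every sample's
        realised community nearly identical and the phylogenetic null
        degenerates.
    selection_floor:
        Lower bound of the Gaussian niche filter: disfavored taxa are
        suppressed to this fraction of their metacommunity weight rather
        than excluded outright (soil background organisms persist at low
        abundance under selection).  0 recovers the pure Gaussian filter.
    """

    name: str
    selection_sd: float = 1.0
    env_values: float | np.ndarray | None = None
    dispersal_mix: float = 0.9
    pool_overlap: float = 0.0
    recruitment: float = 0.6
    drift_sd: float = 1.0
    selection_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in REGIME_NAMES:
            raise ValueError(f"unknown regime {self.name!r}; expected one of {REGIME_NAMES}")
        if not self.selection_sd > 0:
            raise ValueError("selection_sd must be > 0")
        for attr in ("dispersal_mix", "pool_overlap"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{attr} must be in [0, 1], got {v}")
        if not 0.0 < self.recruitment <= 1.0:
            raise ValueError(f"recruitment must be in (0, 1], got {self.recruitment}")
        if self.drift_sd < 0:
            raise ValueError(f"drift_sd must be >= 0, got {self.drift_sd}")
        if not 0.0 <= self.selection_floor <= 1.0:
            raise ValueError(f"selection_floor must be in [0, 1], got {self.selection_floor}")


@dataclass
class SimulatedDataset:
    """A complete synthetic study: table, tree, taxonomy, metadata, traits."""

    table: FeatureTable
    tree: TreeNode
    taxonomy: pd.DataFrame
    metadata: pd.DataFrame
    traits: pd.DataFrame
    true_cultivar_clusters: pd.Series
    true_sample_groups: pd.Series
    regime: AssemblyRegime

    def __post_init__(self) -> None:
        tips = {t.name for t in self.tree.tips()}
        missing = set(self.table.taxon_ids) - tips
        if missing:
            raise ValueError(f"table taxa absent from tree: {sorted(missing)[:5]}")
        if set(self.table.sample_ids) != set(self.metadata.index):
            raise ValueError("sample ids inconsistent between table and metadata")


def _streams(seed: int, names: tuple[str, ...]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def simulate_phylogeny(n_taxa: int, seed: int, birth_rate: float = 1.0) -> TreeNode:
    """Simulate a rooted binary pure-birth (Yule) tree with ``n_taxa`` tips.

    Waiting times between speciation events are exponential with rate
    ``birth_rate × #lineages``; each event splits a uniformly chosen extant
    lineage.  A final waiting time is appended so every pendant branch has
    strictly positive length.  Tips are labelled ``ASV0001`` … in tree order.
    """
    if n_taxa < 2:
        raise ValueError(f"n_taxa must be >= 2, got {n_taxa}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    root = TreeNode()
    first, second = TreeNode(length=0.0), TreeNode(length=0.0)
    root.extend([first, second])
    active = [first, second]
    while len(active) < n_taxa:
        dt = rng.exponential(1.0 / (birth_rate * len(active)))
        for node in active:
            node.length += dt
        idx = rng.integers(len(active))
        parent = active.pop(idx)
        kids = [TreeNode(length=0.0), TreeNode(length=0.0)]
        parent.extend(kids)
        active.extend(kids)
    dt = rng.exponential(1.0 / (birth_rate * len(active)))
    for node in active:
        node.length += dt
    for i, tip in enumerate(root.tips(), start=1):
        tip.name = f"ASV{i:04d}"
    return root


def simulate_trait_optima(
    tree: TreeNode,
    bm_sd: float,
    seed: int,
    rate_decay: float = 0.0,
    normalize: bool = False,
) -> dict[str, float]:
    """Evolve a niche optimum along the tree by Brownian motion.

    The root has optimum 0; each edge adds a Normal(0, bm_sd²·ℓ) increment
    where ℓ is the branch length, so trait variance accumulates with
    evolutionary time and close relatives get similar optima (the
    phylogenetic signal that makes βNTI informative).

    ``rate_decay`` > 0 gives an early-burst variant: the evolutionary rate
    on an edge is damped by exp(−rate_decay · depth of its parent node), so
    trait divergence concentrates deep in the tree, clades acquire distinct
    optima and environmental filtering selects whole clades rather than
    scattered tips — the niche-conservatism pattern assumed by
    nearest-taxon null models.

    With ``normalize`` the tip optima are standardized to mean 0, sd 1, so
    that filter widths (``selection_sd``) are expressed in units of the
    realized trait spread rather than the seed-dependent raw scale (the
    few earliest edges dominate the raw variance, especially under early
    burst).
    """
    if bm_sd < 0:
        raise ValueError("bm_sd must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    values: dict[int, float] = {id(tree): 0.0}
    depths: dict[int, float] = {id(tree): 0.0}
    optima: dict[str, float] = {}
    for node in tree.preorder(include_self=False):
        length = node.length if node.length is not None else 0.0
        parent_depth = depths[id(node.parent)]
        rate = bm_sd * np.exp(-rate_decay * parent_depth)
        val = values[id(node.parent)] + rate * np.sqrt(length) * rng.standard_normal()
        values[id(node)] = val
        depths[id(node)] = parent_depth + length
        if node.is_tip():
            optima[node.name] = float(val)
    if normalize:
        values_arr = np.array(list(optima.values()))
        sd = values_arr.std()
        mean = values_arr.mean()
        if sd > 0:
            optima = {k: (v - mean) / sd for k, v in optima.items()}
        else:
            optima = {k: v - mean for k, v in optima.items()}
    return optima


def _gaussian_filter(optima: np.ndarray, env: float, selection_sd: float) -> np.ndarray:
    return np.exp(-((optima - env) ** 2) / (2.0 * selection_sd**2))


def simulate_community(
    tree: TreeNode,
    optima: dict[str, float],
    regime: AssemblyRegime,
    n_samples: int,
    depth: int,
    seed: int,
    replicate_block: int = 1,
) -> tuple[FeatureTable, pd.Series]:
    """Simulate an ASV count table under one assembly regime.

    Per sample, taxon sampling weights are metacommunity abundance ×
    Gaussian niche filter exp(−(optimum − env)²/(2σ²)); counts are
    multinomial at ``depth``.  The five regimes differ in how the filter,
    the taxon pool and the between-sample mixing are set:

    - ``neutral``: no filter; all samples i.i.d. multinomial draws from the
      metacommunity (drift only).
    - ``homogeneous_selection``: one shared environment value, filter width
      ``selection_sd``; communities pushed toward a common, phylogenetically
      clustered composition.
    - ``heterogeneous_selection``: per-sample environment values spread over
      the optimum range; divergent compositions.
    - ``homogenizing_dispersal``: a fraction ``dispersal_mix`` of every
      sample's reads comes from a single shared community realisation
      (free exchange of members), making pairs more similar than
      independent multinomial noise allows.
    - ``dispersal_limitation``: samples sit on a few isolated islands with
      disjoint (``pool_overlap``-controlled) taxon pools, so cross-island
      pairs share few taxa and drift apart.

    All regimes additionally carry ecological drift: recruitment of a
    weighted taxon subset and lognormal overdispersion of the sampling
    weights (``drift_sd``).  Drift operates per replicate block of
    ``replicate_block`` consecutive samples (replicates of one cultivar
    share a pot, hence one realised community), so replicates are
    consistent enough to survive a replicate-prevalence filter while
    blocks still turn over taxa.

    Returns the count table and a per-sample group label series (island
    ids for dispersal limitation, a single group otherwise).
    """
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    if n_samples < 2:
        raise ValueError(f"n_samples must be >= 2, got {n_samples}")
    taxa = [t.name for t in tree.tips()]
    if set(optima) != set(taxa):
        raise ValueError("optima must cover exactly the tree tips")
    opt = np.array([optima[t] for t in taxa])
    n_taxa = len(taxa)

    rngs = _streams(seed, ("meta", "env", "pools", "drift", "counts"))
    # lognormal(meanlog 0, sdlog 1) metacommunity: realistic rank-abundance
    meta = rngs["meta"].lognormal(mean=0.0, sigma=1.0, size=n_taxa)
    meta /= meta.sum()

    if replicate_block < 1:
        raise ValueError(f"replicate_block must be >= 1, got {replicate_block}")
    n_blocks = int(np.ceil(n_samples / replicate_block))
    block_ids = np.repeat(np.arange(n_blocks), replicate_block)[:n_samples]

    groups = pd.Series(["G0"] * n_samples, index=[f"S{i + 1:03d}" for i in range(n_samples)])
    weights = np.tile(meta, (n_samples, 1))

    floor = regime.selection_floor
    if regime.name == "homogeneous_selection":
        env = 0.0 if regime.env_values is None else float(np.asarray(regime.env_values).ravel()[0])
        filt = _gaussian_filter(opt, env, regime.selection_sd)
        weights = weights * (floor + (1.0 - floor) * filt)[None, :]
    elif regime.name == "heterogeneous_selection":
        if regime.env_values is None:
            # evenly spaced environments (shuffled) guarantee divergent
            # selective pressures across the optimum range
            env = rngs["env"].permutation(np.linspace(opt.min(), opt.max(), n_samples))
        else:
            env = np.broadcast_to(np.asarray(regime.env_values, dtype=float), (n_samples,))
        filt = np.stack([_gaussian_filter(opt, e, regime.selection_sd) for e in env])
        weights = weights * (floor + (1.0 - floor) * filt)
    elif regime.name == "dispersal_limitation":
        # a few isolated "islands": samples on different islands draw from
        # disjoint (pool_overlap-controlled) taxon pools and cannot mix
        n_pools = max(2, int(round(np.sqrt(n_blocks))))
        perm = rngs["pools"].permutation(n_taxa)
        n_shared = int(round(regime.pool_overlap * n_taxa / n_pools))
        shared = perm[:n_shared]
        rest = perm[n_shared:]
        pool_size = len(rest) // n_pools
        masks = np.zeros((n_samples, n_taxa), dtype=bool)
        island = block_ids % n_pools
        for s in range(n_samples):
            own = rest[island[s] * pool_size : (island[s] + 1) * pool_size]
            masks[s, own] = True
            masks[s, shared] = True
        weights = np.where(masks, weights, 0.0)
        groups[:] = [f"pool{i}" for i in island]

    if regime.drift_sd > 0:
        # random proliferation/death: lognormal overdispersion shared by
        # the replicates of one block (one realised pot community)
        jitter = rngs["drift"].lognormal(
            mean=0.0, sigma=regime.drift_sd, size=(n_blocks, n_taxa)
        )
        weights = weights * jitter[block_ids]

    row_sums = weights.sum(axis=1, keepdims=True)
    if np.any(row_sums == 0):
        raise ValueError("a sample received all-zero sampling weights")
    weights = weights / row_sums

    # drift: each block recruits a weighted subset of the available pool
    # (Gumbel top-k = weighted sampling without replacement)
    recruit_mask = np.ones((n_blocks, n_taxa), dtype=bool)
    for b in range(n_blocks):
        w = weights[block_ids == b].mean(axis=0)
        avail = np.flatnonzero(w > 0)
        r_s = max(2, int(round(regime.recruitment * avail.size)))
        if r_s < avail.size:
            keys = np.log(w[avail]) + rngs["counts"].gumbel(size=avail.size)
            chosen = avail[np.argpartition(keys, avail.size - r_s)[avail.size - r_s:]]
            recruit_mask[b] = False
            recruit_mask[b, chosen] = True

    def draw(rng: np.random.Generator, s: int, n_reads: int) -> np.ndarray:
        w = np.where(recruit_mask[block_ids[s]], weights[s], 0.0)
        if w.sum() == 0:  # block recruited outside this sample's support
            w = weights[s]
        return rng.multinomial(n_reads, w / w.sum())

    counts = np.empty((n_samples, n_taxa), dtype=np.int64)
    if regime.name == "homogenizing_dispersal":
        n_shared_reads = int(round(regime.dispersal_mix * depth))
        pooled = weights.mean(axis=0)
        pooled /= pooled.sum()
        shared_counts = rngs["counts"].multinomial(n_shared_reads, pooled)
        for s in range(n_samples):
            counts[s] = shared_counts + draw(rngs["counts"], s, depth - n_shared_reads)
    else:
        for s in range(n_samples):
            counts[s] = draw(rngs["counts"], s, depth)

    table = FeatureTable(
        pd.DataFrame(counts, index=groups.index, columns=taxa), is_relative=False
    )
    return table, groups


def simulate_growth_traits(
    n_cultivars: int,
    n_clusters: int,
    cluster_means: np.ndarray | None = None,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate cultivar-level growth traits with planted cluster structure.

    Traits (shoot fresh/dry weight, leaf count, tuber weight and number)
    are drawn per cultivar around its cluster mean.  ``noise_sd`` is in
    units of the between-cluster spread of each trait: the per-trait noise
    standard deviation is ``noise_sd × std(cluster means of that trait)``,
    so the same scalar controls separability across traits with different
    physical units.  Cultivars are assigned to clusters round-robin.
    """
    if cluster_means is None:
        if n_clusters != DEFAULT_CLUSTER_MEANS.shape[0]:
            raise ValueError("provide cluster_means when n_clusters != 3")
        cluster_means = DEFAULT_CLUSTER_MEANS
    cluster_means = np.asarray(cluster_means, dtype=float)
    if cluster_means.shape[0] != n_clusters or cluster_means.ndim != 2:
        raise ValueError("cluster_means must have n_clusters rows")
    if n_clusters > n_cultivars:
        raise ValueError(f"n_clusters ({n_clusters}) > n_cultivars ({n_cultivars})")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    labels = np.arange(n_cultivars) % n_clusters
    scale = cluster_means.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    values = cluster_means[labels] + noise_sd * scale * rng.standard_normal(
        (n_cultivars, cluster_means.shape[1])
    )
    values = np.clip(values, 0.0, None)
    cols = (
        TRAIT_COLUMNS
        if cluster_means.shape[1] == len(TRAIT_COLUMNS)
        else [f"trait_{j + 1}" for j in range(cluster_means.shape[1])]
    )
    idx = [f"cultivar_{i + 1:02d}" for i in range(n_cultivars)]
    traits = pd.DataFrame(values, index=idx, columns=cols)
    traits.index.name = "cultivar"
    return traits, pd.Series(labels, index=idx, name="true_cluster")


def simulate_taxonomy(
    tree: TreeNode,
    seed: int,
    genus_size: int = 5,
    frac_unclassified: float = 0.15,
) -> pd.DataFrame:
    """Build a ranked lineage table over the tree tips.

    Tips are chunked in tree order (so genera are near-clades) into genera
    of ``genus_size``, genera into families of 3, families into orders of
    3, orders into classes of 2, classes into phyla of 2, all under one
    domain.  A fraction of taxa is left unclassified at genus rank
    (missing values are explicit ``None``, never empty strings), mirroring
    partially resolved reference-database assignments.
    """
    tips = [t.name for t in tree.tips()]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for i, taxon in enumerate(tips):
        g = i // genus_size
        f = g // 3
        o = f // 3
        c = o // 2
        p = c // 2
        rows.append(
            {
                "taxon_id": taxon,
                "domain": "Bacteria",
                "phylum": f"Phylum_{p + 1:02d}",
                "class": f"Class_{c + 1:02d}",
                "order": f"Order_{o + 1:02d}",
                "family": f"Family_{f + 1:02d}",
                "genus": f"Genus_{g + 1:03d}",
            }
        )
    taxonomy = pd.DataFrame(rows).set_index("taxon_id")
    drop = rng.random(len(tips)) < frac_unclassified
    taxonomy.loc[drop, "genus"] = None
    return taxonomy


_FACTOR_VOCAB = {
    "origin": ["Germany", "Poland", "Netherlands", "Czechia", "GreatBritain"],
    "breeding_purpose": ["Table", "Starch", "Industrial", "GeneralPurpose"],
    "earliness": ["MediumLate", "Late", "VeryLate"],
    "tuber_shape": ["Round", "Oval", "RoundOval", "LongOval"],
}


def simulate_dataset(
    n_cultivars: int = 10,
    n_replicates: int = 3,
    n_taxa: int = 150,
    depth: int = 5000,
    regime: AssemblyRegime | None = None,
    bm_sd: float = 1.0,
    rate_decay: float = 1.0,
    trait_noise_sd: float = 0.1,
    seed: int = 0,
    cluster_env: tuple[float, ...] = (0.0, 0.0, 0.0),
) -> SimulatedDataset:
    """Assemble a full synthetic study: tree, table, taxonomy, metadata, traits.

    Cultivars carry planted growth clusters; each sample's environment value
    is its cultivar's cluster value from ``cluster_env`` (identical values
    give homogeneous selection across the whole study; distinct values give
    between-cluster heterogeneity).  Niche optima follow the early-burst
    model with standardized spread, so selection acts on clades and filter
    widths are in trait-sd units.  The default desk scale is 10 cultivars
    × 3 replicates, 150 taxa, depth 5 000; the full-study emulation
    (51 × 3, depth 2 000) is one call away.
    """
    if regime is None:
        regime = AssemblyRegime(
            "homogeneous_selection", selection_sd=0.15, recruitment=0.2,
            selection_floor=0.05,
        )
    streams = _streams(seed, ("tree", "optima", "traits", "community", "factors"))

    def sub(name: str) -> int:
        return int(streams[name].integers(0, 2**31 - 1))

    tree = simulate_phylogeny(n_taxa, seed=sub("tree"))
    optima = simulate_trait_optima(
        tree, bm_sd=bm_sd, seed=sub("optima"), rate_decay=rate_decay, normalize=True
    )
    traits, cultivar_clusters = simulate_growth_traits(
        n_cultivars, 3, noise_sd=trait_noise_sd, seed=sub("traits")
    )

    n_samples = n_cultivars * n_replicates
    if regime.name in ("homogeneous_selection", "heterogeneous_selection"):
        env = np.array(
            [cluster_env[cultivar_clusters.iloc[i // n_replicates]] for i in range(n_samples)]
        )
        regime = replace(
            regime,
            name="heterogeneous_selection" if len(set(env)) > 1 else "homogeneous_selection",
            env_values=env if len(set(env)) > 1 else float(env[0]),
        )
    table, groups = simulate_community(
        tree, optima, regime, n_samples=n_samples, depth=depth, seed=sub("community"),
        replicate_block=n_replicates,
    )
    taxonomy = simulate_taxonomy(tree, seed=sub("tree"))

    frng = streams["factors"]
    cultivar_factors = {
        name: frng.choice(vocab, size=n_cultivars) for name, vocab in _FACTOR_VOCAB.items()
    }
    breeding_year = frng.integers(1900, 2015, size=n_cultivars)
    records = []
    for i, sid in enumerate(table.sample_ids):
        ci = i // n_replicates
        cultivar = traits.index[ci]
        records.append(
            {
                "sample_id": sid,
                "cultivar": cultivar,
                "replicate": i % n_replicates + 1,
                "growth_cluster": ["high", "medium", "low"][cultivar_clusters.iloc[ci]],
                "breeding_year": int(breeding_year[ci]),
                **{name: cultivar_factors[name][ci] for name in _FACTOR_VOCAB},
            }
        )
    metadata = pd.DataFrame(records).set_index("sample_id")

    return SimulatedDataset(
        table=table,
        tree=tree,
        taxonomy=taxonomy,
        metadata=metadata,
        traits=traits,
        true_cultivar_clusters=cultivar_clusters,
        true_sample_groups=groups,
        regime=regime,
    )
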