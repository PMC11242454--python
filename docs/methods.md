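# Methods

`rhizobiome` implements the analysis chain used to relate plant growth
phenotypes to rhizosphere microbial community structure: growth-based
clustering of cultivars, alpha/beta diversity with factor testing,
null-model partitioning of community assembly processes, and compositional
co-occurrence networks — validated end-to-end against a synthetic-data
generator with known ground truth.

## The synthetic community model

No generative model is available for real rhizosphere data, so the
generator adopts the minimal model under which phylogenetic null-model
inference is informative: **niche filtering of a phylogenetically
conserved trait, plus ecological drift**.

1. **Phylogeny.** A pure-birth (Yule) tree with exponential waiting times
   (rate = number of extant lineages) and a final pendant extension, so
   every branch length is strictly positive.
2. **Niche optima.** Brownian motion along the tree (variance ∝ branch
   length). An optional *early-burst* mode damps the evolutionary rate by
   `exp(−rate_decay · node depth)`, concentrating divergence deep in the
   tree so that clades carry distinct optima — the niche-conservatism
   regime that nearest-taxon statistics assume. Optima can be standardized
   to unit spread so that filter widths are in trait-sd units; the raw
   trait scale is dominated by the two or three earliest edges and varies
   several-fold between seeds.
3. **Metacommunity.** Relative abundances drawn once from a lognormal
   (meanlog 0, sdlog 1), giving a realistic rank-abundance curve.
4. **Selection.** Per sample, taxon weights are metacommunity abundance ×
   Gaussian filter `exp(−(optimum − env)²/(2σ²))`, optionally lifted by a
   `selection_floor` so disfavored taxa persist at a small fraction of
   their background abundance (soil organisms are suppressed by the
   rhizosphere environment, not eradicated). Homogeneous selection shares
   one environment value; heterogeneous selection spreads evenly spaced
   environment values (shuffled) across samples.
5. **Drift.** Two mechanisms, both operating per *replicate block* (the
   replicates of one cultivar share a pot, hence one realised community):
   lognormal overdispersion of the weights (`drift_sd`), and recruitment
   of a weighted subset of the pool (`recruitment`, Gumbel top-k =
   weighted sampling without replacement). Counts are then multinomial at
   the requested depth, so every sample sums exactly to the sequencing
   depth.
6. **Dispersal regimes.** Homogenizing dispersal allocates a fraction
   `dispersal_mix` of every sample's reads from a single shared community
   realisation (members exchanging freely produces correlation *beyond*
   multinomial noise — mixing expected weights alone cannot push
   Raup–Crick below its null floor). Dispersal limitation places samples
   on ≈√(number of blocks) islands with disjoint
   (`pool_overlap`-controlled) taxon pools.

### Why drift is not optional

β-mean-nearest-taxon distance between two communities that share a taxon
counts that taxon at distance 0 — in the observed data *and in every
shuffled null*. If two samples contain identical taxon sets, βMNTD is 0
under any permutation and the null has zero variance: the pair is
unclassifiable. The phylogenetic null model is informative only when
communities turn over taxa, and detection of selection further requires
community richness well below the pool size (richness ≈ 5–15% of taxa in
the regime-recovery settings); when samples cover most of the pool, the
nearest random taxon is already close and the null loses contrast. The
drift parameters exist to put the generator in this regime, which is the
regime real ASV tables occupy (thousands of taxa, strong between-sample
turnover).

### What the generator does not emulate

Sequencing error, chimeras, PCR and primer bias, contamination,
compositional library-size variation, fungal ITS length variation, or any
temporal dynamics. Passing the validation suite therefore shows that the
statistics recover *planted* structure under this model's assumptions —
not that the pipeline is robust to artefacts real amplicon data may carry.

## Preprocessing

Singleton removal (total count exactly 1) → replicate-prevalence filter
(keep a taxon iff some cultivar has it in ≥ 2 of 3 replicates; the rule is
existential over cultivars because a universal rule empties the table) →
total-sum scaling. The core microbiome uses ≥ 80% prevalence of samples
with relative abundance strictly > 0.01% within each group, partitioned
into disjoint Venn regions with their read proportions.

## Growth clustering

Traits are z-scored (n−1 denominator). k is chosen by the elbow of the
within-cluster sum of squares **on the log scale** (max second difference
of log WSS over k = 2..k_max−1): on the raw scale the k=1→2 drop dominates
whenever clusters are roughly collinear — which performance gradients are —
and the raw elbow returns k=2 regardless of the true number of groups. A
mean-silhouette criterion is available; best silhouette < 0.25 raises a
"weak structure" warning. k-means (25 restarts, best WSS) is mirrored by
Ward-variance agglomeration (scipy `ward` = the ward.D2 convention on
Euclidean distances). For k = 3 clusters are ranked high/medium/low by the
mean of row-summed z-scores, ties broken by mean tuber weight. Group
separation uses ANOSIM on Euclidean distances between scaled trait
vectors (the same metric the clustering uses).

## Diversity

Richness, Shannon entropy (nats) and Simpson dominance λ = Σp² are
computed from within-sample proportions (so TSS is a no-op for them);
because conventions differ on the direction of "Simpson's index", 1−λ is
reported alongside λ. Weighted UniFrac is the normalized variant
(Σb|A−B| / Σb(A+B) over branches, range [0,1]), computed by a vectorized
branch–incidence construction and cross-checked against scikit-bio and a
branch-enumeration oracle. PCoA is the Gower-centred eigendecomposition
(scikit-bio), negative eigenvalues reported. PERMANOVA is the one-factor
distance-based SS partition (SS_total = Σd²/N), with factor-wise
independent tests rather than a joint order-dependent model; ANOSIM uses
ranked distances with denominator N(N−1)/4. Permutation p-values use
(count+1)/(n_perm+1). Pairwise differential abundance uses two-sided
rank-sum tests (exact enumeration for untied samples ≤ 20 per group,
tie-corrected normal approximation otherwise) with Benjamini–Hochberg
adjustment across the whole family.

## Assembly null models

βMNTD is abundance-weighted, conspecifics included (a shared taxon
contributes 0); an unweighted variant sits behind a flag. βNTI permutes
taxon labels across the tree tips (1000 shuffles by default; the
validation experiments use 199–500 and state so) and reports
(obs − null mean)/null sd per pair; zero-spread nulls are flagged
unclassifiable, never coerced to 0. βNTI is invariant to uniform branch
rescaling (asserted to 1e-6 for ×10). RCbray operates on counts before
TSS: each null fixes a sample's observed richness (species drawn without
replacement ∝ occurrence frequency, Gumbel top-k) and total count
(multinomial ∝ mean relative abundance of the drawn species), and
RCbray = 2·[(#null < obs) + ½(#null = obs)]/n_null − 1. Classification:
βNTI > 2 heterogeneous selection; βNTI < −2 homogeneous selection;
otherwise RCbray > 0.95 dispersal limitation, < −0.95 homogenizing
dispersal, else undominated. Boundary values (|βNTI| = 2, |RCbray| = 0.95)
fall on the stochastic/undominated side. Per-group summaries use
within-group pairs by default (an all-pairs option exists) and exclude
unclassifiable pairs from the denominator while reporting their count.

## Co-occurrence networks

ASVs are agglomerated to genus; taxa unclassified at genus are pooled
under "U. <deepest classified rank>". The clr transform uses a pseudocount
of 1. Edges must pass the *conjunction* of |r| ≥ 0.3, two-sided t-test
p ≤ α (defaults mirror the bacterial α = 10⁻⁴; each criterion is
toggleable) and local FDR ≤ 0.2. The lFDR fits a two-component empirical
null on Fisher-z correlations (null N(μ₀,σ₀) from the median and scaled
IQR, marginal by Gaussian KDE, π₀ capped at 1); below 200 tests the
empirical-null fit is unstable and BH q-values are substituted with a
logged notice. Modules come from greedy (Clauset–Newman–Moore) modularity
maximization on |r| weights; hubs are nodes whose per-component leading
eigenvector score (scaled to unit max per component) strictly exceeds the
95% empirical quantile, with a 1e-9 tolerance so exact ties (regular
graphs) yield no hubs. Topology metrics: components counted over the full
genus universe (isolated genera are singleton components), density over
the same universe, mean local clustering over degree-≥2 nodes, average
shortest-path length over reachable pairs, and natural connectivity
ln((1/N)Σe^λ) of the unweighted adjacency over connected nodes — reported
both raw and normalized by (N − ln N). The raw value is the one strictly
monotone under edge deletion; the normalization makes networks of
different order comparable but lets a single dense clique outscore two,
which is why the planted-structure discrimination experiment compares the
raw value.

## Validation experiments (tests/test_acceptance.py, scripts/acceptance.py)

The motivating study's headline numbers derive from its real sequencing
data and are not reproducible from synthetic input, so validation is
property-based:

- **Null calibration** — neutral communities at 30 samples × 150 taxa ×
  depth 5000, 500 shuffles, 10 seeds: fraction of |βNTI| > 2 must stay
  ≤ 0.10 (observed ≈ 0.03–0.05).
- **Regime recovery** — each of the five regimes at strong settings
  (16 samples × 600 taxa × depth 2000, 199 nulls; early-burst normalized
  optima) must be the modal classified process in ≥ 8/10 seeds.
- **Oracle equivalence** — weighted UniFrac, βMNTD, cophenetic distances,
  average path length, modularity values (≤ 6 nodes, exhaustive partition
  search) and eigenvector hubs against brute-force oracles on 50 random
  instances each, to 1e-8.
- **Statistical calibration** — PERMANOVA/ANOSIM type-I error 0.05 ± 0.02
  over 500 null simulations (99 permutations each, n = 20); rank-sum + BH
  false-discovery proportion ≤ 0.07 over 500 all-null 200-feature panels.
- **Growth recovery** — 51 cultivars, cluster separation ≈ 5–7
  within-cluster sds per trait (noise_sd 0.2 of the between-cluster
  spread): k = 3 selected, ARI ≥ 0.9, and k-means/Ward agreement in
  ≥ 9/10 seeds.
- **Network discrimination** — planted correlated genus blocks (10 and 12
  members, within-block r ≈ 0.9 after clr) over 50 high-variance
  background genera; removing the 12-block must strictly lower connected
  nodes, edges and raw natural connectivity, and modules must recover the
  blocks (ARI ≥ 0.8). Background variance is set so the clr-centering
  artifact stays below the 0.3 correlation threshold.
- **Filter determinism** — the preprocessing chain against exhaustive
  evaluation of all 2⁶ presence patterns on a 2-cultivar toy.

The problem sizes above were chosen so the full validation suite runs in
a few minutes on one CPU; the acceptance script additionally runs a
desk-scale end-to-end pipeline (10 cultivars × 3 replicates, 300 taxa,
depth 5000, 199 nulls) and reports its ANOSIM R, growth-cluster PERMANOVA
R² and within-cluster homogeneous-selection fraction as computed.

## Known limitations

- Selection detectability depends on pool density: at low taxon counts or
  near-complete per-sample pool coverage βNTI honestly loses power, and
  the desk-scale end-to-end emulation consequently shows a much smaller
  homogeneous-selection fraction than a full-scale study would.
- The lFDR empirical-null fit assumes most correlations are null; on
  panels dominated by signal it will under-estimate π₀.
- The Raup–Crick null conditions on occurrence frequency and mean relative
  abundance computed from the analysed table itself; with very few samples
  these are noisy and the tails are conservative.
- greedy modularity is a heuristic; the oracle test asserts the reported Q
  equals the exhaustive evaluation of the *found* partition and never
  exceeds the exhaustive optimum, not that the optimum is always attained.
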