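# Methods

This note documents the statistical models, numerical conventions and
design choices behind germdiv, in the spirit of the model documentation
shipped by packages like statsmodels or msprime.

## Dominant-marker statistics

Dominant fingerprints (SRAP, SCoT, ISSR, RAPD) observe each locus only
as band presence/absence; heterozygotes are indistinguishable from
dominant homozygotes, so all statistics operate on the band-presence
frequency p computed over non-missing calls. Per band:

- gene diversity H = 2p(1−p), the two-state form of 1 − Σpᵢ², maximal
  at 0.5 when p = 0.5;
- PIC = 1 − (p² + q²) − 2p²q² (Botstein's measure reduced to two
  states), maximal at 0.375; PIC ≤ H always, with equality only for
  fixed bands;
- band informativeness I_b = 1 − 2|0.5 − p|.

Per primer: PB counts bands with both states observed among non-missing
calls (a strict criterion; a 95% minor-frequency criterion is available
via `criterion="95"` but off by default, since band data rarely warrant
a frequency cutoff). The effective multiplex ratio is E = PB·(PB/n); the
polymorphic-fraction form PB/n can be selected with
`e_formula="fraction"` — the literature prints E under several
incompatible definitions, so the convention in force is recorded in the
pipeline run log. MI averages PIC over all n scored bands before
multiplying by PB (`mi_bands="polymorphic"` switches to averaging over
polymorphic bands only). Discriminating power follows Tessier:
DP = 1 − Σᵢ pᵢ(Npᵢ−1)/(N−1) over the distinct multi-band patterns,
algebraically equal to the probability that two genotypes drawn without
replacement differ in pattern — the brute-force pairwise computation is
kept as a test oracle. Genotypes with any missing call inside a primer
are excluded (N adjusted) for DP only; per-band statistics use per-band
denominators.

Panel summaries report percent polymorphism both as the unweighted mean
of per-primer percentages and as the pooled ratio of totals; published
tables often mix the two, so both are labeled explicitly.

## Colorimetry

Chroma C\* = √(a\*²+b\*²) and hue H° = atan2(b\*, a\*) mapped to
[0°, 360°). The single-argument arctan(b\*/a\*) seen in many protocol
sections is quadrant-ambiguous and undefined at a\* = 0; the
two-argument form is the CIE standard and is used unconditionally. At
the achromatic point a\* = b\* = 0 hue is undefined and stored as
missing; when the color feature matrix feeds Euclidean distance the
pipeline imputes such missing hues with the column mean (documented
policy, applied only to the color layer where missingness is structural
rather than informative).

## Diversity indices

Shannon H′ (natural log), Gini–Simpson λ = 1 − Σpᵢ² and Pielou
J = H′/ln S are computed per genotype over a nonnegative profile: band
calls directly for the marker layer, min-max-scaled variables for trait
and color layers (scaling to [0,1] makes mixed data nonnegative without
letting any variable dominate). For 0/1 band profiles every shown band
carries equal weight, so J = 1 and H′ = ln S; the informative variation
is in S. J is undefined (reported missing) for profiles with a single
nonzero category, and all-zero profiles are excluded from summary blocks
with a warning.

## Distances

- Euclidean: optional z-scoring with the population SD (divisor N),
  chosen so results are bit-reproducible and documented; constant
  features are dropped with a warning; missing values are a hard error —
  silent imputation would distort every downstream dendrogram, so
  imputation must be explicit.
- Gower: quantitative features contribute |x−y|/range, qualitative
  features 0/1 mismatch; features missing in either member of a pair
  are excluded from numerator and denominator (pairwise deletion); a
  pair with no comparable feature is an error. When all features are
  binary qualitative, Gower equals simple matching (property-tested).
- Binary: simple matching (mismatches/compared) and Jaccard
  (1 − both/either), missing calls excluded pairwise.
- Pearson: profile correlation with 1−r as the associated
  dissimilarity (range [0,2]); constant profiles are rejected by name.

Qualitative traits entering Euclidean distance or PCA are ordinal-coded
by their declared level order, then standardized. Dummy coding is the
principled alternative for nominal traits; ordinal coding is the default
because germplasm descriptors are usually recorded on ordered scales.

## UPGMA and cophenetic validation

UPGMA is implemented directly: at each step the pair of clusters with
minimal average-linkage distance merges at that distance, and distances
to the merged cluster are size-weighted means — equivalent to
re-averaging all member pairs, which the test suite verifies against a
brute-force reference on 1000 random matrices (n ≤ 8) and against
scipy's average linkage. Merge heights are the raw merge distances
(hclust convention), keeping cophenetic distances on the input scale.
Ties are broken by the lexicographically smallest pair of cluster keys
(a cluster's key is its smallest leaf label), making output
deterministic. Newick export places a node at ultrametric depth
height/2, so leaf-to-leaf path lengths equal cophenetic distances.

The cophenetic correlation coefficient is the Pearson correlation
between input and tree-implied distances over all leaf pairs; it equals
1 exactly when the input is ultrametric, and values ≳ 0.8 are
conventionally read as a faithful dendrogram.

## Tanglegram entanglement

With u_ℓ, v_ℓ the 1-based positions of leaf ℓ in the two displayed
orders, entanglement = Σ|u_ℓ−v_ℓ|^L / Σ|i−(m+1−i)|^L, the worst case
being one order the full reversal of the other; 0 means aligned. L = 1.5
is the dendextend default and ours. Untangling searches over internal-
node flips: `step1side` sweeps the moving tree's nodes root-to-leaf,
accepting a flip only on strict decrease and repeating sweeps until one
passes unchanged (strictness guarantees termination); `step2side`
alternates sides to joint convergence; `random` keeps the best of
seeded random rotations and the initial state. The greedy result never
exceeds the initial entanglement, and on trees with ≤ 6 leaves
step2side restarted from 10 random rotations reaches the exhaustive
2^(n−1) × 2^(n−1) minimum in every tested instance. Matched-leaf
reports cut both trees at k and pair the clusters by maximal overlap
(Hungarian assignment).

## PCA

Eigendecomposition of the correlation matrix (covariance when
`standardize=False`), population convention throughout. Scores are the
standardized data projected on the orthonormal loadings, so full-rank
reconstruction is exact. Eigenvector signs are fixed by making each
column's largest-magnitude loading positive. Kaiser selection keeps
eigenvalues > 1 and never returns zero components.

## Synthetic panel generator

The generator emulates the data shapes of a germplasm diversity study:
n_genotypes = 32 accessions in n_groups = 4 latent groups (species
clusters or cultivar families), a 12-primer SCoT-like panel of 204
bands (a 26-primer SRAP-like layout is provided too), 19 quantitative
and 17 qualitative traits, and CIELab triplets for six organ regions
(flower slip, eye, sepal, petiole, dark and silver leaf lamina).

Each group g carries a latent coordinate u_g ~ N(0, I₃) shared by all
layers; every layer derives its group effects from projections of u_g,
so between-group relatedness is consistent across markers, traits and
colors. This is the generator's central design decision: shared group
*membership* alone does not couple the layers' dendrogram hierarchies —
the deep block structure of each tree would be independent — whereas a
shared geometry makes related groups similar in every layer, which is
what real multi-layer characterization of the same collection looks
like.

- Bands: baseline frequency ~ Beta(2,2); a shifted_fraction = 0.5 of
  bands is group-informative with ±δ/2 offsets (δ = group_shift = 0.6
  by default, so informative bands differ by 0.6 in presence frequency
  between groups on opposite sides). Half of the informative bands
  (coupled_fraction) take their offset signs from median splits of the
  latent coordinates along random directions (markers tracking
  relatedness); the rest use i.i.d. signs (homoplasious markers),
  ensuring every group pair remains distinguishable even when two
  groups sit close in latent space. Frequencies are clamped to
  [0.02, 0.98] — no band is ever deterministically fixed — and calls
  are Bernoulli. The simulation operates on band-presence frequencies
  directly rather than diploid allele dosage, matching what dominant
  scoring observes.
- Quantitative traits: group means from latent projections scaled so
  the RMS between-group separation is Δ = 3 noise SDs by default.
- Qualitative traits: groups ranked along a random latent direction and
  binned into levels; a genotype shows its group's preferred level with
  probability 0.7.
- Colors: per organ and channel, group means = center + 10·(ŵ·u_g)
  around realistic CIELab centers (L\* 55, a\* 10, b\* 15), within-group
  SD 3, L\* clipped to [0, 100].

Group membership is a seeded random permutation of equal-sized blocks,
so two independently simulated panels share neither membership nor
geometry. All randomness flows from one integer seed through a single
numpy Generator.

What the generator does **not** emulate: linkage between bands (each
band is conditionally independent given the group), realistic color
gamut constraints beyond the L\* bounds, trait-trait correlation beyond
what shared group structure induces, genotyping error, and unequal or
nested group sizes. Tests passing on these panels therefore demonstrate
algorithmic correctness and sensitivity under idealised group
structure, not robustness to the messier correlation patterns of real
collections.

## Problem sizes and observed behaviour

The verification suite uses: 1000 random matrices (3 ≤ n ≤ 8) for the
UPGMA oracle; 300 random instances (N ≤ 6) for the DP oracle; 12 tree
pairs (4–6 leaves) against the exhaustive rotation search; 20 simulated
panels for cluster recovery (mean adjusted Rand index of the k = 4
UPGMA cut against truth, observed ≈ 0.95 at the default conditions) and
20 panel pairs for the coupling comparison (mean post-untangle
entanglement ≈ 0.02–0.05 for same-panel marker/trait trees versus
≈ 0.30 for trees from independently simulated panels). These sizes give
stable Monte-Carlo estimates while keeping the whole suite fast.

## Known limitations

- The entanglement minimiser is greedy; global optimality is only
  verified for small trees, and on large trees different untangle
  methods reach different local minima (the method in force is recorded
  in every result).
- Ordinal coding of qualitative traits imposes an ordering that may be
  arbitrary for truly nominal descriptors.
- Missing-data policies differ by metric (pairwise deletion for
  Gower/binary, hard error for Euclidean/PCA) and are intentional, but
  mean that switching metrics on incomplete data changes the effective
  sample per pair.
- Diversity indices on min-max-scaled continuous profiles depend on the
  scaling choice; they are comparable within a run, not across studies
  using different profile constructions.
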