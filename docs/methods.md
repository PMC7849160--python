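# Methods

This note documents the statistical procedures, the synthetic study design
the package emulates, the numerical conventions, and the design choices made
where the problem was genuinely open.

## The AVD stability index

For one group of k replicate communities the variation degree of feature i
in sample j is |a_ij| = |x_ij − x̄_i| / δ_i, with x̄_i and δ_i the
within-group mean and standard deviation of the feature's (rarefied)
abundance. The group's average variation degree is

    AVD = Σ_ij |a_ij| / (k · n),

where the sum runs over all feature × sample terms and n counts the features
with δ_i > 0. We read the normalization k·n as a per-term average — the only
reading under which the quotient is a mean of |a| values.

Conventions, each exposed as a parameter:

* **δ uses the sample standard deviation (ddof = 1).** Consequence: a k = 2
  group of non-constant features gives AVD = √2/2 exactly (with ddof = 0 it
  is exactly 1). The identity is asserted in the test suite and documents
  the choice.
* **Zero-variance features are excluded from both the numerator and n.**
  They carry no variation signal and would otherwise contribute 0/0. A
  sensitivity mode keeps them in n with zero deviation.
* **No normality filter.** The index is motivated by approximately normal
  replicate variation but is computed for every non-constant feature;
  nothing gates features on a normality test by default.

Properties worth knowing when interpreting AVD: because each feature's
z-scores satisfy Σ_j z²_j = k − 1, the per-feature mean |z| is bounded by
√((k−1)/k) ≈ 1 and equals √(2/π) ≈ 0.798 for i.i.d. Gaussian variation.
AVD is therefore *not* a variance: multiplying a feature's abundances by a
constant leaves it unchanged. What moves AVD is the *shape* of replicate
variation — balanced bimodal profiles (a feature alternating between two
states across replicates) push the mean |z| toward 1, while one-outlier
profiles push it down toward 2/√k. This is the property the synthetic
generator exploits (below) and the reason AVD responds to replicate
turnover and regime shifts rather than to noise amplitude per se.

## Normalization regimes

* **Rarefaction** — one seeded multivariate-hypergeometric draw per sample
  (without replacement) to a fixed depth, default 11,020 reads; samples
  below depth are dropped and reported. Averaging across repeated draws is
  available but not the default, matching the common single-rarefaction
  convention.
* **Relative abundance** — columns divided by their totals (idempotent).
* **Size-factor log transform** — median-of-ratios size factors over the
  features detected in all samples, rescaled to geometric mean 1, followed
  by log2(count/size factor + 1). This is the size-factor normalization
  family used by count-based differential-abundance tools; the full fitted
  mean–dispersion variance-stabilizing transform is intentionally out of
  scope because the transform's role here is only a robustness check on the
  AVD group ordering.
* **Row z-scores** (for heatmap-style displays) — mean 0, sd 1 per row,
  ddof = 1, constant rows are errors.

## Phylogenetic metrics and the betaNTI null model

Faith's PD is root-inclusive (the spanning subtree includes the path to the
root), delegated to scikit-bio on presence/absence vectors; a toggle for the
root-exclusive variant is not provided because richness is reported
alongside. Weighted UniFrac is computed by post-order branch accumulation:
each branch contributes length × |p_A − p_B| of the relative abundance
below it, normalized by length × (p_A + p_B) so values lie in [0, 1]. The
implementation is exact for float inputs and is checked against a literal
per-branch enumeration oracle to 1e-12.

betaMNTD between two communities is the two-direction mean of each taxon's
patristic distance to its nearest taxon in the other community,
abundance-weighted by default (a presence-only toggle exists). The null
model shuffles taxon labels across *all* tree tips — the richness- and
abundance-preserving "taxa labels" null — with one fresh permutation per
draw shared by all sample pairs; 999 draws by default (199 in the bundled
analysis drivers for speed). betaNTI is the z-score of the observed
betaMNTD against this null; pairs whose null sd collapses below 1e-12 are
reported undefined rather than scored. Classification: betaNTI > 2 →
variable selection; betaNTI < −2 → homogeneous selection; |betaNTI| ≤ 2 →
stochastic. The homogeneous-selection threshold is the standard negative
tail; a sign-free reading of the threshold pair would contradict the
stochastic band and is treated as a typo in the source convention.

Statistical power of betaNTI depends on the concentration of the null: with
few taxa per community the null betaMNTD distribution is broad and even a
maximally clustered pair rarely falls below −2. The bundled constructions
therefore use 128-tip trees with 16–20 taxa per community.

## Co-occurrence networks

Edges: Spearman correlation (average ranks, two-sided p via the t
approximation) across samples for every category pair; BH adjustment over
all defined pairs; an edge is kept when |r| > 0.75 **and** q < 0.01. The
magnitude reading of the correlation threshold is deliberate — it is what
admits negative (co-exclusion) edges, and the significance threshold is
applied to the adjusted q by default (raw-p mode available). Pairs
involving a constant category are undefined and excluded from the BH
family.

Topology conventions: avgK = 2m/n; avgCC averages local clustering with
degree-<2 nodes contributing 0; APD averages shortest-path lengths over
connected pairs only (the connected fraction is reported); GD =
avgK/(n−1); M is Newman–Girvan modularity of a seeded Louvain partition of
the unweighted graph. Random ensembles are uniform G(n, m) draws with the
empirical node and edge counts (default 100 draws), summarized with the
same conventions. Isolated categories are dropped from the drawn graph but
visible through the reported node counts.

Node roles follow the Guimerà–Amaral plane: Zi is the within-module degree
z-score using the population sd of the node's module (σ = 0 ⇒ Zi = 0);
Pi = 1 − Σ_s (k_is/k_i)²; thresholds Zi = 2.5 and Pi = 0.62 split
peripheral / connector / module hub / network hub. The functional
vocabulary maps category names (case- and punctuation-insensitive) to
specialized metabolic, broad metabolic, genetic information processing,
cellular processes, environmental information processing and organismal
systems; the specialized and broad lists are fixed enumerations, everything
else is user-extensible, and unknown names report as `unmapped` rather than
being guessed. Edge-sign summaries pool specialized + broad as the
metabolic aggregate and cellular + environmental information processing as
the environmental-responses aggregate; edges bridging aggregates are
tallied separately.

## Classifier comparison and permutation importance

The continuous per-sample stability score (the sample's mean variation
degree) is discretized into quantile classes — default 3 bins, near-equal
counts, with hard errors when ties collapse a bin — because error-rate
comparison across classifier families needs a classification target; a
regression mode (permutation drop in R²) is provided for users who prefer
not to bin. Seven stock scikit-learn families (decision tree, gradient
boosting, bagging, k-nearest neighbors, SVM, random forest, multilayer
perceptron) are evaluated under identical repeated stratified k-fold splits
(default 10 folds), so differences reflect the learners. Importance is
computed per cross-validation fold: fit the forest on the training part,
permute one feature column in the held-out part (several repeats), record
the accuracy drop; the average over folds is the mean decrease accuracy.
Ranks follow feature identity, not column position, and everything is
deterministic given the seed.

## The synthetic study design

The generators emulate the data-generating structure of a
dilution-to-extinction × pH microcosm experiment: 4 dilution levels
(10⁻¹ … 10⁻¹⁰) × 5 target pH (4.5 … 8.5) × 6 replicates = 120 samples,
200-taxon regional pool, multinomial sequencing at 15,000 reads. Sizes were
chosen so the full suite runs in minutes on one CPU.

* **Phylogeny** — a random ultrametric hierarchy whose node heights scale
  as (clade size)^a with log-normal jitter. Small clades are shallow and
  basal splits deep, emulating the nested structure of microbial
  phylogenies; this is what makes clade membership a strong patristic
  signal for the betaNTI constructions.
* **pH optima** — a Brownian trait on the tree blended with independent
  noise (signal knob, default 0.8), rank-mapped onto the pH range, so
  betaMNTD-based inference has the trait–phylogeny correlation it assumes.
* **Dilution** — each level retains a decreasing fraction of the pool
  (1.0 / 0.70 / 0.45 / 0.25), sampled once per level because replicate
  microcosms of a level share an inoculum.
* **pH selection** — Gaussian fitness kernel around each taxon's optimum
  with strength rising with dilution, plus an optional hard niche width
  (taxa beyond the width die out). The default scenario keeps widths
  infinite; the `strong_selection` preset narrows them with dilution.
* **Regrowth evenness** — realized abundances are flattened
  (pool × fitness)^(1−e) with e rising with dilution (0 / 0.3 / 0.6 / 0.8):
  after dilution, survivors regrow toward carrying capacity, compressing
  dominance. Without this, the heavy log-normal tail makes many taxa
  sparse-by-sampling in the diluted levels, which biases AVD downward
  through one-outlier presence profiles.
* **Replicate instability** — occupancy turnover (each taxon independently
  absent from a replicate with probability q) plus log-normal noise, with
  q rising with dilution (0.05 / 0.20 / 0.30 / 0.45). Turnover reshapes
  per-taxon profiles toward the balanced bimodal high-|z| limit, which is
  what raises AVD; pure variance scaling would not (see the AVD section).
* **Functional profiles** — a Gaussian copula over ~38 named categories
  with two planted correlation blocks (specialized and broad metabolic,
  within-block ρ = 0.95), opposite linear dilution trends for the two
  blocks, and two keystone categories (nitrogen metabolism; phosphonate and
  phosphinate metabolism) whose abundance declines with the per-sample
  instability score. The per-sample (not group-level) coupling is what
  gives the keystones information that no trend-following category
  duplicates, so permutation importance can single them out.
* **Consortium** — 7 members; each removal condition alternates replicates
  between two compositional regimes separated by balanced-sign log shifts
  (magnitude 0.3, ×4 for the keystone removal; factor 1 erases the
  keystone). Balanced signs keep the two regimes distinct after
  compositional closure; the keystone removal drives every member bimodal
  and its AVD well above the rest.

What the generators do **not** emulate: real sequencing error, chimeras and
compositional artifacts of amplicon data; taxon–taxon interactions;
realistic KEGG pathway structure or annotation noise; temporal dynamics
within the incubation. Passing tests demonstrate that the statistics
recover effects of the planted kind at realistic sizes — not that any
particular real soil behaves this way.

## Numerical choices and degenerate inputs

Seeds: every stochastic routine takes an explicit seed; the pipeline fans
one global seed into per-stage seeds via `numpy.random.SeedSequence.spawn`.
Rarefaction requires integer counts and errors when every sample is below
depth. Constant features: excluded from AVD's n, flagged undefined in
correlation, errors in z-scoring. Empty communities are errors for PD,
UniFrac and betaMNTD. Degenerate betaNTI null sds (< 1e-12) mark pairs
undefined; runs abort if more than 5% of pairs degenerate. Ties in
Spearman get average ranks; ties collapsing a quantile bin are errors. The
Louvain partition and modularity are deterministic for a fixed seed;
two-cluster toy graphs (two disjoint triangles → M = 0.5) pin the
convention. Missing table cells are errors, never zeros.

## Known limitations

* AVD compares groups of equal k most cleanly; the index's bounded range
  (≈ 2/√k … √((k−1)/k)) means large-k groups compress differences.
* The betaNTI implementation supports one tree for all samples; per-sample
  trees (e.g. from bootstrap placement) are out of scope.
* Weighted-graph modularity and compositionality-aware correlation
  (SparCC-style) are intentionally not implemented; the network module
  operates on relative abundances with rank correlations.
* The functional vocabulary ships only the categories named in its source
  lists plus common KEGG level-3 names; real tables will contain unmapped
  categories, which are reported, not guessed.
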