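# Methods

`lupine` implements an analysis pipeline for detecting cryptic population
structure in continuous wildlife populations from diploid microsatellite
genotypes, with spatial validation from sample coordinates and telemetry.
This note documents the models, the estimators, the numerical choices, and
what the synthetic data generator does and does not emulate.

## Data model

Genotypes are unordered pairs of integer allele sizes; a genotype is either
fully observed or wholly missing (a half-missing call is coerced to missing
on input, since none of the downstream estimators can use a single gene
copy). Allele identity is the integer size itself — no binning or
recalibration is applied. Coordinates must be planar/projected, in km; all
distances and polygon areas are Euclidean/planar. The choice of projection is
the user's: the package never performs geodesy.

## Admixture model and MCMC (`lupine.admixture`)

The clustering model is the standard Bayesian admixture mixture: individual
`i` has membership proportions `q_i ~ Dirichlet(α, …, α)` over `K` clusters;
each allele copy at locus `l` originates from cluster `k` with probability
`q_ik` and is then a draw from that cluster's allele frequencies `p_kl`. Two
frequency priors are available:

* **independent**: `p_kl ~ Dirichlet(λ=1)`;
* **correlated (F-model)**, the default: `p_kl ~ Dirichlet(π_l (1−F_k)/F_k)`
  with shared ancestral frequencies `π_l ~ Dirichlet(1)` and per-cluster
  drift intensities `F_k ~ Uniform(0.001, 0.5)`.

Updates: the allele-copy origins `z`, the memberships `q` and the cluster
frequencies are conjugate Gibbs draws (the F-model prior is
Dirichlet-conjugate given `z`, so cluster frequencies are Gibbs-updated under
both priors — no Metropolis step is needed there); `π_l` moves by a
symmetric two-allele mass-shift Metropolis step, `F_k` by random-walk
Metropolis, and `α` by random-walk Metropolis with a Uniform(0, 10] prior.
Missing genotypes contribute nothing to the likelihood. Frequencies are
floored at 1e−12 to keep logarithms finite.

**Data log-probability.** `ln Pr(X|K)` is summarized by the
mean-minus-half-variance heuristic over post-burn-in log-likelihood samples,
the same approximation the field's standard program reports. It is *not* an
unbiased marginal-likelihood estimator: on tiny tables where the exact
Dirichlet-multinomial marginal can be computed (`k1_log_marginal`), the
heuristic sits a few percent high (e.g. ≈1.3 log units on a 5-individual ×
2-locus table) because the posterior of the log-likelihood is not Gaussian.
The test suite asserts agreement at 15% relative on such tables, which is
the fidelity this estimator actually offers; its role in practice is only
comparative across K.

**Chain lengths.** Desk-scale defaults are 50,000 sweeps with 10,000
burn-in. The long-chain profile used for publication-grade runs (2.5M total
sweeps, 500k burn-in) is available as `PipelineConfig.paper_faithful()`. The
recovery experiments in `lupine.experiments` use much shorter chains
(1,200–2,000 sweeps) on small simulated datasets, where convergence is fast;
the chain lengths there were chosen so that replicate `ln Pr(X|K)` estimates
are stable enough for the ΔK denominator (see below), and the experiment
sizes (e.g. 3 × 20 individuals, 15 loci) keep the full 20-seed experiments
within minutes on one core.

**K is reported, never auto-decided.** The pipeline emits `ln Pr(X|K)`, the
Evanno table, and replicate-consistency diagnostics; the analyst picks K.

## Model-choice diagnostics (`lupine.clustering`)

* **Replicate alignment** resolves label switching by maximum-weight
  bipartite matching (Hungarian algorithm) on column-wise Pearson
  correlation, with a squared-error fallback for constant columns. The
  between-run similarity statistic is `1 − mean |q_a − q_b|/2 ∈ [0, 1]`.
* **Evanno ΔK**: `ΔK(K) = |L''(K)| / sd(L(K))` from replicate means; entries
  undefined at the boundary are NaN-flagged, never zero-filled; a zero
  replicate sd yields `+inf` with a warning. ΔK tends to inherit noise from
  the lnP estimator's replicate variance at well-supported K, which is why
  the recovery experiment needs either long-enough chains or several
  replicates.
* **Hierarchical re-clustering** re-runs the sampler inside each inferred
  cluster. The stopping rule is: a node is a leaf when mean `ln Pr(X|K)` is
  maximized at K=1, when the ΔK-selected K does not improve mean
  `ln Pr(X|K)` over K=1, or when the subset is smaller than twice the size
  floor (default 6, the smallest group size the pipeline is designed to
  resolve). ΔK itself is undefined at K=1, so "ΔK supports no split" has to
  be operationalized through the lnP comparison.
* **PCA + k-means (DAPC-style)**: individuals are encoded as allele-count
  vectors (missing → column mean), centred, reduced by SVD, clustered by
  multi-start k-means over a K grid, and scored with
  `BIC(K) = n ln(WSS/n) + K ln n`; linear discriminant axes on the chosen
  partition give membership probabilities. Note that the BIC bottoms out at
  the true K only when enough PCs are retained: in low dimension k-means
  keeps cutting noise variance and the BIC keeps decreasing, which is one
  reason the 80-PC convention exists.

## Admixed classification (`lupine.classify`)

Per-cluster cut-offs operationalize the "visible gap" rule reproducibly: for
cluster k, take the memberships of its members (argmax = k) plus anyone with
`q_ik > 0.5`, sort, and place the cut-off at the midpoint of the widest gap
whose endpoints both exceed 0.5. If no gap reaches `min_gap` (default 0.05)
or the cluster has fewer than 3 members, a fallback cut-off (default 0.80)
is used and flagged. Individuals at or above their home cut-off are
non-admixed; individuals whose maximum membership does not exceed 0.5 are
unassigned (they cannot be attributed to any group); everyone else is
admixed. Whether cut-offs should be estimated from members only or from all
individuals with any membership is genuinely open; the member-plus-q>0.5
rule is this package's choice.

## Population-genetic statistics (`lupine.popgen`)

* **Diversity**: per locus `He = 1 − Σ p²` (headline value; the unbiased
  `2n/(2n−1)` variant is also emitted), `Ho` = observed heterozygote
  fraction, `F = 1 − Ho/He` averaged over polymorphic loci.
* **Rarefaction**: `AR(g)` and private `pAR(g)` follow the standard
  combinatorial rarefaction (per allele, `1 − C(N−N_i, g)/C(N, g)`,
  evaluated through log-gamma). The rarefaction standard "smallest sample
  size" is read as gene copies: `g = 2 × min group n` by default, with loci
  skipped per group when their non-missing copies fall below g. These
  quantities are verified in the suite against exhaustive subset
  enumeration.
* **Lynch–Ritland relatedness** with locus weights and both reference
  orderings averaged. Reference frequencies default to the group's own
  members, which centres unrelated pairs near `−1/(n−1)`; a whole-table
  reference (`freq_reference="total"`) preserves absolute relatedness within
  groups of relatives and is the right choice when groups are small families.
* **Differentiation**: multiallelic Weir–Cockerham θ (the AMOVA ϕST
  equivalent for allele-identity distances), with a label-permutation test
  using the `(1 + hits)/(n_perm + 1)` convention so p is never 0. Jost's D
  uses Nei–Chesser bias-corrected Hs/Ht with harmonic-mean sample sizes;
  per-locus D values are averaged arithmetically (a locus-averaged-H variant
  is available via `pooling="mean_h"`). Note θ has a small negative O(1/n)
  bias for identical groups.
* **HWE / LD**: Monte-Carlo exact HWE test (gene copies shuffled into
  genotype tables, Levene/Haldane conditional probability) and a G-statistic
  permutation LD test on two-locus genotype tables; Bonferroni correction
  within each test family.
* **Mantel IBD**: genetic distance is 1 − proportion of shared alleles
  (pairwise, loci with missing data in the pair excluded); geographic
  distance is planar Euclidean; one-tailed permutation p. Shared-allele
  distance is used rather than an â-type regression statistic — a documented
  divergence from inter-individual statistics some programs use. Cluster
  structure alone produces positive Mantel correlations (clustering
  masquerades as isolation by distance), and the suite asserts exactly that
  on clustered simulations.

## Spatial structure (`lupine.spatial`)

Members of a group (membership > 0.5) are chained by single linkage at an
adjacency distance (default 50 km ≈ reported mean natal dispersal distance
of ~32 km plus margin; the "adjacency" notion is otherwise undefined in the
field and is exposed in config). The largest chain is the territory core;
`P_total` is its convex hull, `P_non_admixed` the hull of its non-admixed
members. The circularity between hull membership and disperser status is
resolved in one pass: blocks first, hulls from the largest block, dispersers
second, no iteration. A disperser is a non-admixed individual outside its
own group's `P_total`; its host is the group whose polygon contains it
(possibly none). Telemetry `P_s` is the convex hull of all of an animal's
locations over its full monitoring period; a territory counts as overlapped
when the intersection reaches 1% of the `P_s` area (0 restores strict
any-intersection). Degenerate geometries (<3 non-collinear points) are
flagged, excluded from area statistics, and handled by point-in-polygon
fallbacks.

## Migration (`lupine.migration`)

Recent migration rates follow the two-generation assignment model:
an individual sampled in group l is a resident, a first-generation migrant
from q, or a second-generation migrant from q; the prior given the migration
matrix is `P(first from q) = P(second from q) = m[l][q]` and
`P(resident) = 2 m[l][l] − 1`, which forces `m[l][l] ≥ 2/3`. Likelihoods:
residents and first-generation migrants follow inbreeding-adjusted
Hardy–Weinberg proportions in the home/source frequencies respectively;
second-generation migrants draw one copy per locus from each. Because each
migrant class occurs with probability `m[l][q]`, a dataset containing only
first-generation migrants at fraction f centres the posterior near f/2 — a
property to keep in mind when interpreting rates as "migrant fractions".
Posterior means are reported as proportions; converting to numbers of
migrants (Nm) requires an external population-size estimate and is left to
the user.

The sampler is sweep-based Metropolis-within-Gibbs: one iteration draws every
individual's ancestry state exactly (states are conditionally independent
given the other parameters, so this is a vectorized Gibbs step) and makes one
Metropolis move per migration-matrix row, per group's allele frequencies
(symmetric two-allele mass shift, window `0.1 × delta_alleles`), and per
group's inbreeding coefficient. The three `delta` parameters (defaults 0.3,
0.7, 0.6) are proposal step sizes, as in the convention of the program this
module follows. Desk defaults are 4,000 sweeps / 1,000 burn-in / thinning 5
— roughly 10⁶ elementary updates at n ≈ 200, far beyond what the small
datasets here need; `paper_faithful` uses 100k/10k sweeps (≈ 2×10⁷ elementary
updates). Row sums and the diagonal constraint are asserted on every retained
sample. "CI does not include zero" is operationalized as a lower 95% bound
above 1e−4, since the prior support excludes exact zero; on very small
groups the posterior lower bound rarely drops below ~1e−3, so edge lists at
that default threshold should be read together with the posterior means.

## Sample selection (`lupine.selection`)

Quality filter first (default: drop samples with >20% missing genotypes),
then relative-avoidance: samples closer than 10 km, or inside the same
circular pack buffer (area 100 km² → radius √(100/π) km), form conflict
sets; within a set, at most 2 samples are kept per 5-year window, windows
binned on a May-to-May annual cycle anchored at a fixed epoch (1900) so that
re-running on the kept set is a no-op. Preference order inside a window:
adults, then lower missingness, then earlier collection date, then sample id
— the last two tie-breaks exist to make the rule a total order, hence
deterministic and order-invariant. A pairwise mode (each kept sample blocks
others within 5 cycle-years) is available behind a flag; whether window
binning or pairwise gaps is the "right" reading of the field protocol is
ambiguous, and the window reading is the default here.

## Synthetic data (`lupine.simulate`)

The generator draws from the same correlated-frequency (F-model) process the
clustering sampler fits: ancestral frequencies Dirichlet(1), cluster
frequencies `Dirichlet(π (1−F)/F)`, one-hot memberships for non-admixed
individuals, Dirichlet memberships for an admixed minority, allele copies
drawn cluster-of-origin-first. Defaults emulate the north-west Iberian wolf
dataset the pipeline was designed around: 11 clusters with sizes
(13, 17, 21, 12, 14, 6, 53, 30, 11, 11, 19), 46 loci, 6 alleles per locus,
drift 0.2 (giving per-group He ≈ 0.55–0.65 and pairwise ϕST ≈ 0.05–0.25),
admixed fraction 0.3, 3% missing data, 7 planted dispersers. Admixed
individuals draw memberships from a Dirichlet with a dominant home component
(mean q_home ≈ 0.65) and the external mass biased toward the geographically
nearest cluster, so that most admixed individuals remain attributable
(max q > 0.5) and group mean-membership rows show 0–2 external contributors
above 5%, as in real parapatric systems.

Territories are non-overlapping discs on a grid with a 60 km edge-to-edge
gap — deliberately wider than the 50 km adjacency default, so that a planted
disperser is, *by construction*, spatially separate from its own group's
core and the disperser-recall experiment tests the detector rather than the
geometry's luck. Collar tracks are uniform draws within the home territory,
with an optional excursion batch in the nearest neighbouring territory.

What the generator does **not** emulate: mutation processes (no stepwise
mutation model), pedigrees and family structure within clusters, an
isolation-by-distance continuum (clusters are exchangeable given the
layout), irregular territory shapes, non-uniform space use, or informative
missingness. Tests passing on these simulations therefore demonstrate
correctness of the estimators and detectors under the fitted model's own
assumptions — not robustness to the many ways real wolf data violate them.

## Experiment scales

`lupine.experiments` fixes the problem sizes used by the test suite and the
reproduction script: ΔK recovery on 20 datasets of 3 × 20 individuals × 20
loci at the default drift, 3 replicate chains of 2,000 sweeps per K (at
fewer loci or shorter chains the recovery rate hovers within sampling error
of the 80% design target, so the experiment scale is set where the verdict
reflects the method rather than seed luck); membership recovery on
10 two-cluster datasets at drift 0.3; migration CI calibration on 20
two-group datasets drawn from the migration model's own generative process
(m = 0.08 off-diagonal); disperser and telemetry checks on the full
wolf-shaped configuration; HWE type-I calibration on 300–400 simulated
Hardy–Weinberg loci; Mantel-null uniformity on ~100 independent matrix
pairs. These sizes are the package's own desk-scale choices and are
documented here so results are reproducible.
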