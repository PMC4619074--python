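# Methods

This note documents the models, estimators, defaults and design decisions in
`micnet`, and what the synthetic-data tests do and do not establish about
real data.

## Data model and per-platform preparation

Each platform is an `OmicsBlock`: a feature-by-sample real matrix with
per-feature metadata (gene symbol, X-chromosome flag, control role). The
canonical cohort layout has 46 samples across five histology classes
(9 yolk sac tumor, 18 teratoma, 8 dysgerminoma, 4 mixed, 7 normal adjacent).

**Methylation.** β = M / (M + U) with M, U the methylated/unmethylated
fluorescence signals; β ∈ [0, 1] by construction and both-zero signals give a
logged missing value. The customary +100 denominator stabilizer is available
(`offset`) but off by default, keeping the plain two-term ratio. QC removes a
locus when its detection p-value exceeds `detection_alpha` (0.05) in at least
`fail_fraction` (0.25, inclusive boundary) of samples, and, when `drop_x` is
on, any X-linked locus: X-linked methylation tracks sex rather than tumor
biology in a mixed-sex cohort. On the study-scale panel of 1505 loci with 16
detection failures and 84 X-linked loci (disjoint sets) this leaves 1405.

**miRNA counts.** Positive-control normalization computes per-sample factors
f_s = (cohort mean of per-sample positive-control geometric means) /
(sample s's geometric mean) and scales the non-control rows; this equalizes
the implied positive-control geomeans exactly and preserves within-sample
rank order. Negative-control handling is an upper-quantile *background
floor*: counts below the per-sample 0.75 quantile (linear interpolation) of
the negative controls are raised to it and flagged. A floor was chosen over
subtraction or upper-quartile scaling because it cannot produce negative
counts and keeps downstream negative-binomial modeling valid; the quantile is
configurable. Order of operations is positive-control scaling first, then the
background floor. Normalized counts remain real-valued; the count test
rounds them (documented below).

**qPCR panel.** ΔCt(g, s) = Ct(g, s) − mean over housekeeping genes of
Ct(·, s); housekeeping rows are dropped from the output, and a sample missing
any housekeeping Ct gets all-missing ΔCt rather than a silently biased
reference. ΔCt is invariant to per-sample plate shifts by construction.

## Differential analysis

**Exact negative-binomial test.** For two groups of count vectors the test
conditions on the total K = K_A + K_B, models each group sum as NB with mean
n_g·m̂ and size n_g / d̂ (m̂ the pooled mean, d̂ the dispersion), and reports
the total probability of all splits (a, K−a) whose probability does not
exceed that of the observed split — a two-sided exact tail on the discrete
distribution. p-values are clamped into (0, 1].

*Dispersion.* The per-feature moment estimate d̂ = (v̂ − m̂)/m̂² (pooled
within-group variance, floored at 1e-8) is extremely noisy with 2–3
replicates per group and makes the test anticonservative (measured type-I
error 0.12 at nominal 0.05 with n = 3 vs 3). The default therefore combines
it with a mean–variance lowess trend fitted across features, taking the
larger of the per-feature and fitted variances (`dispersion_mode="max"`, the
conservative sharing rule of classic count-based DE methods; measured type-I
error 0.05, KS distance from uniform 0.024, and full power at an 8-fold
shift). `"per_feature"` and `"fit"` modes are available; the trend needs
≥ 10 features and falls back to per-feature below that.

**BH adjustment** uses the standard step-up formula
(q_(i) = min_{j ≥ i} m·p_(j)/j, capped at 1) via statsmodels. Note that BH is
*not* idempotent (re-adjusting adjusted values can change them); the tested
invariants are monotonicity and q ≥ p.

**Fold changes** use ΔΔCt = mean ΔCt(A) − mean ΔCt(B), fold = 2^(−ΔΔCt),
with a flag for ≥ 3-fold changes in either direction (|log₂ fold| > 1.58).
The group significance test on ΔCt is Welch's t (unequal variances are
expected between histologies); zero-variance equal-mean genes get p = 1.

**Clustering** of sample columns uses city-block distance with average
linkage via scipy, with pairwise-complete distances rescaled by the fraction
of shared features. Scipy's deterministic tie handling is accepted as the
tie-break rule; dendrograms export to Newick.

## Fusion and encoding

Phenotypes become numeric rows: age in years passes through; sex, location
and histology are mapped by injective code tables. The default histology
codes follow a low-to-high severity ordering (normal adjacent 0, teratoma 1,
dysgerminoma 2, YST 3, mixed 4), location ovary 0 / testis 1 / extragonadal
2, sex male 0 / female 1. **These defaults are an explicit assumption** — any
ordering of a categorical variable imposes structure on its correlations —
and are fully overridable in `EncodingConfig`.

Diploid genotype calls are encoded on a transition/transversion-grouped
scale, the idea being that transitions (a↔g, c↔t) are likelier than
transversions and should sit near the homozygotes they connect:
t/t −4.0, c/t −3.0, c/c −2.0, g/t −0.5, c/g −0.2, a/t 0.2, a/c 0.5, a/a 2.0,
a/g 3.0, g/g 4.0. Calls are lowercased and order-normalized (g/a ≡ a/g).

`build_fused_matrix` stacks ≥ 2 blocks, tags every row with its platform,
drops control/housekeeping rows, and restricts columns to samples complete in
every block (logged). miRNA values enter fusion as normalized counts,
untransformed; a log2(x+1) transform is deliberately not applied by default.
`subset_samples` removes one histology (e.g. the YSTs) for the repeat
analysis; with the canonical missingness pattern the fused cohort has 40
samples (8 YST), and the non-YST subset 32.

## Pearson + MIC all-pairs association

Every unordered row pair gets a Pearson r and a MIC on pairwise-complete
observations (n_used recorded; pairs with fewer than `min_pairwise_n` = 8
shared points, or a constant vector, yield missing values).

The MIC of (x, y) is the maximum over grids G = k columns × l rows, subject
to k·l ≤ B(n), of I_G(x; y) / log₂ min(k, l), where I_G is the mutual
information of the induced 2-D histogram. Defaults follow the canonical MINE
settings: B(n) = n^α with α = 0.6 (floored at 4 so a 2×2 grid is always
admissible) and clump factor c = 15.

*Estimation.* For each l, the y-axis is equipartitioned into l rows (tied
values never split); x-axis candidate cut points are restricted to clump
boundaries (maximal runs of x-consecutive points in one row; superclumps cap
their number at c·k_max), and a dynamic program over the additive
per-bin decomposition of H(P) − H(P, Q) finds the optimal k-bin partition
for every k ≤ B/l. Both orientations are computed and the maximum taken, so
the estimator is exactly symmetric. Ties are handled by stable sorting.

*Small-n regime.* The equipartition heuristic can sit far below the true
grid optimum on very small samples — precisely where MIC is least
trustworthy anyway (a warning is emitted below 30 points). When
n ≤ `small_n_exact_threshold` (16) the admissible grid space is tiny, so the
estimator switches to exhaustive enumeration of all admissible grids, which
is both exact and fast there; `mic_exact_oracle` exposes the same
enumeration (n ≤ 12, axes ≤ 4) as an independent verification oracle, and
the test suite checks containment (estimate ≤ exhaustive optimum, within
0.05) on random instances.

## Network and hubs

Edges keep pairs that (a) span two different platforms (phenotype counts as
its own platform) and (b) reach the threshold (default 0.75) in |Pearson|
(absolute by default — anticorrelation is biologically meaningful; a flag
restores signed behavior) or MIC; the edge weight is the larger qualifying
magnitude. Single-linkage grouping at a fixed threshold is mathematically
the connected components of the thresholded graph, which is how it is
implemented (networkx); component ids are deterministic (smallest member).
Hubs are nodes of degree ≥ 4 (configurable; "four or more" is the adopted
reading of the hub criterion). Hub and neighbor gene symbols, deduplicated,
with symbol-less features (phenotypes, unannotated probes) dropped, form the
hub gene list. Networks export to GraphML and TSV for external layout tools;
no layout is computed in-package.

## Enrichment with a random-list control

Upstream-regulator over-representation is a hypergeometric upper tail
P[X ≥ overlap] against a user-supplied GMT annotation restricted to the
profiling universe, BH-adjusted across regulators. The random-gene-list
control draws `k_random` = 3 sets of the same size uniformly from the same
universe and re-runs the enrichment; a regulator is reported significant
only if its real q < 0.05 *and* its real p is strictly below the minimum of
its random-set p-values — the most conservative reading of "compare with the
random lists" (a q-only mode exists). The control is seeded and
deterministic.

## Synthetic cohort generator

The generator emulates the study conditions, not any particular dataset:

- **Samples**: 46 (9/18/8/4/7 across histologies), with ages, sex and
  location drawn from histology-conditional distributions mimicking the
  cohort's demographics. Per-platform missingness masks default to 3 miRNA
  samples (1 YST, 1 mixed, 1 normal) and 4 stem-cell samples (1 YST, 1
  teratoma, 2 normal) whose union leaves 40 complete samples with 8 YSTs.
- **Methylation**: per-locus logit-normal β (baseline logit ~ N(0, 1.5));
  detection p-values ~ U(0, 0.04) for passing loci, with exactly
  `n_detection_fail` loci given p > 0.05 in 25–50 % of samples; exactly
  `n_x_linked` loci flagged X-linked, disjoint from the failure set by
  construction so the QC arithmetic is exactly recoverable (an
  `allow_overlapping_flags` switch exists for stress tests).
- **miRNA**: NB counts with per-feature base means log-uniform on [20, 2000]
  and dispersions log-uniform on [0.05, 0.5] (variance ≥ mean preserved);
  per-sample lognormal lane factors (σ = 0.3) multiply everything, giving
  positive-control normalization something to remove; 6 positive controls on
  a geometric ladder scaled by the lane factor, 8 Poisson(2) negative
  controls.
- **qPCR**: gene Ct ~ N(25, 2) + per-sample plate shift (σ = 0.8) + noise;
  5 housekeeping genes at N(16, 1) + the same shift, so ΔCt removes it.
- **Genotypes**: 4 SNPs drawn per-sample from Hardy–Weinberg equilibrium at
  allele frequency 0.3 — a neutral default in the absence of population
  frequencies.
- **Planted structure**: each `HubSpec` adds a latent z per sample
  (histology-driven: standardized severity code + N(0, 0.3); otherwise
  standard normal) and loads the hub feature and ≥ 4 spokes (spanning ≥ 2
  platforms) on f(z) with f linear, quadratic (centered, Pearson-null) or
  sinusoidal, scaled by `effect_size`. Defaults: noise_sd 0.5, effect_size
  1.5 (three times the noise), hub feature noise noise_sd/4 (the hub is the
  driver proxy); methylation spokes receive the effect on the logit scale at
  baseline 0 (β ≈ 0.5, the quasi-linear region); miRNA spoke means are
  linear in the latent (slope 0.3·effect) floored at 2 % of base expression,
  with dispersion 0.05 and base mean ≥ 500 so that NB noise does not swamp
  the planted correlation on the raw-count scale. The default cohort plants
  one six-spoke hub (a stem-cell gene driving 3 CpG loci and 3 miRNAs), so
  every hub edge is cross-platform. The truth record stores planted edges
  and hubs for recovery testing.

**What the synthetic tests do not show.** The generator produces mutually
independent non-planted features, clean control probes, exact HWE genotypes
and Gaussian noise; real platforms have correlated probe blocks, batch
structure, and heavier-tailed noise. Passing recovery tests demonstrates the
pipeline's correctness and its statistical behavior under the stated model,
not performance guarantees on arbitrary real cohorts.

## Problem sizes in the test suite

The heavier simulation tests run on a unit-scale cohort (`reduced_spec`: 30
CpG / 30 miRNA / 15 genes, identical 46-sample and missingness structure and
the same planted hub), which gives a 77 × 40 fused matrix and 2926 pairs per
cohort. Hub-recovery and null-hub checks use 50 seeds each; the NB
calibration uses 2000 null features (n = 3 vs 3) and 200 shifted features;
the MIC oracle comparison uses 100 random instances with n ≤ 12. The
study-scale cohort (1505 loci) is generated and QC'd in the tests, but
all-pairs analysis at that scale (~2.9 M pairs) is reserved for real use.

## Numerical choices

- Tolerances: positive-control geomean equality asserted to 1e-9 relative;
  MIC symmetric bit-for-bit (canonical argument ordering in the exhaustive
  path); cohort generation bit-reproducible for a given seed, with TSVs
  written at %.17g so the disk round trip is lossless.
- Degenerate inputs: constant vectors yield missing correlations (logged);
  empty sample intersections, zero positive controls, missing housekeeping
  references and out-of-range p-values raise `ValidationError`.
- The exact NB tail comparison uses a 1 + 1e-7 relative slack when comparing
  split probabilities to the observed one, so ties of equal probability are
  always included (this is what makes the all-identical-counts case return
  exactly 1).
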