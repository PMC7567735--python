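# Methods

## The individual metabolic connectome

A subject's FDG-PET volume, already in template space and parcellated by a
90-region anatomical atlas, carries one intensity sample per voxel. After
dividing by the global mean uptake over the atlas support (so intensities are
in normalized-uptake units with pooled mean 1), each region contributes a
sample of its voxel-intensity distribution. The metabolic connection between
regions i and j is defined through the Jeffreys (symmetric Kullback-Leibler)
divergence between the two distributions,

    D(P, Q) = ∫ [ P(x) log(P(x)/Q(x)) + Q(x) log(Q(x)/P(x)) ] dx,
    KLS(P, Q) = exp(−D(P, Q)) ∈ (0, 1],

with P and Q estimated by Gaussian-kernel density estimation. Two regions
whose voxels share one intensity law get weight near 1; disjoint intensity
distributions get weight near 0. Assembling all R(R−1)/2 pairs gives a
symmetric, fully weighted connectivity matrix per subject (90 × 90, 4005
unique edges, at the default parcellation). The diagonal is stored as zero by
convention — KLS(P, P) = 1 mathematically, but self-loops must not enter
graph metrics. The conventional group-level comparator correlates regional
mean uptakes across subjects (Pearson r between region columns).

### Numerical choices in the divergence core

* **Kernel and bandwidth.** Gaussian kernel; Silverman's rule per region,
  h = 0.9·min(sd, IQR/1.34)·n^(−1/5). Zero-spread samples fall back to
  h = 10⁻³·max(|mean|, 1) so degenerate regions still yield a proper density.
* **Grid.** 512 equally spaced points per unordered pair, spanning the pooled
  samples of the pair ± 3·max(h). A `grid_mode="global"` option evaluates
  each region once on a single subject-wide grid and reuses it for all pairs;
  on normalized subjects (one common intensity scale) the two modes agree to
  about 0.1% relative while the global mode is roughly R/2 times faster. The
  demo pipeline and the replicated calibration studies use the global mode;
  the library default stays per-pair, which remains exact when region scales
  differ arbitrarily.
* **Density floor.** Before taking logs, each density is floored at 10⁻⁶ of
  its own maximum and renormalized (shared floor per pair on the global-grid
  path, so grid regions outside both supports contribute exactly zero). The
  floor bounds the log-ratio where the kernel estimate carries no
  information: far outside a region's samples the kernel tail decays on the
  bandwidth scale, far faster than any plausible true tail, and an
  unregularized log-ratio there inflates the divergence by tens of percent.
* **Integration.** Trapezoid rule; with 512 points the quadrature error is
  orders of magnitude below the statistical error of the estimate.

### Measured accuracy of the divergence estimator

Against the Gaussian closed form D = (σ₁²+Δμ²)/(2σ₂²) + (σ₂²+Δμ²)/(2σ₁²) − 1,
with 5000 samples per side, the estimator's bias is below ~2% for mild
separations and rises to ~8% at Δμ = 3σ; the per-estimate sampling noise is
4–9% SD per cell. That noise is irreducible for a plug-in estimator at this
sample size: it is driven by the extreme order statistics of one sample
falling inside the bulk of the other (each such voxel swings the
cross-entropy term), and for small divergences by the fluctuation of the
empirical divergence itself (≈ Δμ/√n per side). When location and scale
separation are both extreme (Δμ ≈ 3σ and σ-ratio ≈ 2, i.e. nearly disjoint
supports), the floored tail dominates the integral and worst-case errors of
12–18% occur regardless of floor, bandwidth inflation, log-ratio capping,
analytic noise-bias correction, or tail extrapolation (all of which were
evaluated and rejected — each trades one corner of the sweep against
another). The oracle validation therefore sweeps Δμ/σ ∈ {0.6 … 3.0} crossed
with σ-ratios {1.0 … 1.4} — the regime of globally normalized PET uptake,
where scale differences between regions are moderate — averages six
independent draws per cell, and requires agreement within 10% plus two
standard errors of that average, with the sweep-mean error held to 10%
strictly (observed ≈ 3–4%). Divergences between same-law samples shrink as n
grows; at n = 5000 identical-distribution edges have median KLS weight above
0.99.

## Validation statistics

* **Edge-wise difference pattern.** Weights are Fisher-Z transformed
  (atanh, clipped at ±(1−10⁻⁷)), each unique edge is compared between groups
  with Welch's t (pooled-variance optional), and Benjamini–Hochberg FDR is
  applied across the R(R−1)/2 unique edges only; significance is q < α.
  Edges with zero variance in both groups get p = 1 with a warning.
* **Lobe aggregation.** The share of significant edges attributed to a lobe
  counts, by default, edges with at least one endpoint in the lobe
  (`touch`), divided by the total number of significant edges — so shares
  need not sum to one; a `within` mode (both endpoints) is provided. The
  shipped atlas lobe map assigns the 90 regions to frontal / parietal /
  occipital / temporal / other (insula, cingulate, deep grey); membership is
  a CSV and can be replaced.
* **Stability.** The similarity of m networks is the mean Spearman rank
  correlation between the vectorized upper triangles of all m(m−1)/2
  unordered pairs (190 pairs at m = 20). Average ranks resolve ties.
* **Regional dissimilarity.** For region i, each subject contributes its
  connectivity profile (row i, self-entry removed); V_i is the mean of
  1 − Spearman ρ over subject pairs, so V_i ∈ [0, 2] with 0 for identical
  profiles. The map is Z-normalized across regions (population SD; a
  constant map yields all-zero Z), and lobe means with pairwise Welch tests
  summarize it.

## Graph-metric feature set

Seven global and five regional properties on the weighted, fully connected
network (no thresholding by default; an optional proportional threshold
exists for sensitivity analyses). Path-based metrics use edge length 1/w.

| property | definition |
|---|---|
| clustering coefficient | mean Onnela per-node clustering (geometric mean of triangle weights normalized by max w) |
| characteristic path length | mean shortest 1/w-distance over finite off-diagonal pairs |
| small-worldness | (C/C_null)/(L/L_null) against 20 seeded weight-permutation nulls |
| global efficiency | mean inverse shortest distance |
| transitivity | total triangle intensity over total degree pairs |
| assortativity | Pearson r of endpoint strengths over edges (0 if strengths are constant) |
| modularity | best weighted Louvain quality over 10 seeded restarts, resolution 1 |
| degree (regional) | node strength (sum of incident weights) |
| betweenness (regional) | unnormalized weighted betweenness on 1/w lengths |
| local efficiency (regional) | global efficiency of the neighbor-induced subgraph |
| vulnerability (regional) | (E − E₋ᵢ)/E, the relative global-efficiency drop on deleting node i |
| local clustering (regional) | Onnela per-node clustering |

The null model for small-worldness permutes the upper-triangle weights
(destroying topology, preserving the weight multiset exactly); a network of
i.i.d. weights therefore has S ≈ 1. The feature vector concatenates the 7
global values with 5 × R regional values named `metric__region` — 457
entries for the 90-region atlas. All metrics are checked against exhaustive
brute-force path/triangle enumeration on small random graphs.

## Prognostic pipeline

* **Metabolic connectome expression (MCE).** An L1-penalized logistic
  regression on the standardized feature table selects a sparse subset of
  properties; MCE is the resulting linear score (training-set
  standardization frozen into the model). The penalty path spans two decades
  below the smallest all-zero lambda; stratified 10-fold cross-validated
  binomial deviance picks lambda by the one-SE rule (sparser; `min`
  optional), and an optional unpenalized refit of the selected set is
  provided. Classification performance is summarized by the Mann–Whitney
  AUC.
* **Survival models.** Cox proportional-hazards fits use Efron tie handling
  (via lifelines). Continuous covariates are standardized to unit SD on the
  fitting data so hazard ratios read per SD; binary covariates keep their
  scale. Four covariate sets mirror the standard comparison: clinical
  (MMSE, APOE ε4, age, sex), connectome (MCE, age, sex), pattern (an
  externally computed group-level pattern expression score accepted as an
  input column, never computed here; the demo substitutes a synthetic
  stand-in), and combined. Rank-deficient designs raise instead of fitting.
* **Evaluation.** The prognostic index (PI) is the linear predictor under
  the training standardization. Harrell's C-index counts pairs (i, j) with
  t_i < t_j and an observed event in i as comparable; PI ties count one
  half. The Kaplan-Meier stratification splits at the median PI (ties to
  low-risk), compares strata by log-rank test, and reports the high-vs-low
  hazard ratio from a one-covariate Cox fit.

## Synthetic cohorts

The generator emulates parcellated, globally normalized PET subjects, not
PET physics. Per region, voxel intensities are Gaussian (lognormal behind a
flag) with location μ and scale σ in normalized-uptake units; defaults
μ ≈ 1, σ = 0.1, 500 voxels per region (no published per-region voxel counts
exist for the atlas, so fixture sizes are configurable). Between-subject
variability is additive Gaussian jitter on μ only (default SD 0.02), which
keeps the Gaussian divergence oracle exact. Group differences enter solely
through per-region overrides of (μ, σ). Conversion times follow an
exponential proportional-hazards model: rate = baseline·exp(β·z) with β in
log-hazard per SD of named features, administrative censoring at the
follow-up horizon (default 36 months, matching a 3-year follow-up design).
A single cohort seed spawns per-subject substreams, so cohorts are
byte-identical across runs and adding a group never perturbs another
group's draws. NIfTI fixtures assign each region a contiguous voxel block
in a small grid; round-trip through extraction recovers each region's
sample multiset.

What the generator does not emulate — scanner PSF, scatter, attenuation,
partial-volume effects, anatomically realistic region geometry, and spatial
autocorrelation between neighboring voxels — means passing tests demonstrate
the statistical machinery is correct under its stated model, not that the
method's published effect sizes transfer to real cohorts.

### Demo cohort conditions

The one-command demo simulates stable and progressive groups (default 30
subjects each, 20 regions, 500 voxels/region). Baseline regional means span
roughly ±10% of the global mean — the scale of real normalized-uptake
differences between regions — so networks carry rank structure shared
across subjects. The progressive group's regional hypometabolism is a −0.08
location shift with a 1.2× scale increase in a quarter of the regions.
Synthetic clinical covariates follow the characteristics reported for MCI
conversion cohorts (MMSE ≈ 28.4 vs 26.9, APOE ε4 positivity ≈ 45% vs 64%,
age ≈ 71 vs 73 years). Conversion hazards are predominantly network-driven:
the degree of the two most-altered regions acts protectively at HR ≈ 2.5
and 1.8 per SD, with a mild MMSE contribution (HR ≈ 1.2 per SD), baseline
rate 0.03/month. Train/test splits alternate subjects within group.
On cohorts this small the demo selects the penalty by CV minimum (the
one-SE rule often returns the empty model below ~100 training subjects) and,
if the LASSO still selects nothing, falls back to the single most
label-correlated property fit unpenalized.

### Replicated study sizes

Replicated calibration studies scale the per-subject problem down so the
replicate counts stay at their stated values: the FDR calibration/power
study uses 200 replicates of 30 + 30 subjects, 20 regions, 40 voxels/region,
256 grid points on the subject-wide grid; selection recovery uses 50
replicates of n = 300 with 5 informative of 457 features at 1 SD effect;
survival recovery uses n = 500 (single fit), 100 null replicates for CI
coverage, and 200 replicates for the log-rank null. These sizes are stated
here as the package's study conditions and are arguments to the
corresponding functions.

## Known limitations

* The divergence estimator's accuracy degrades to 12–18% when location and
  scale separation are simultaneously extreme (see above); weights there are
  near zero anyway, so network topology is barely affected, but absolute
  divergence values in that regime should not be over-interpreted.
* Lobe percentages depend on the counting convention (`touch` vs `within`);
  published percentages rarely state theirs.
* The AD-meta-ROI is a configurable label set; no specific composition is
  claimed as canonical.
* The pattern expression score is an external method's output and is only
  accepted as a precomputed column.
* Headline clinical numbers from controlled-access cohorts (within-group
  similarity 0.789/0.731, AUC 0.875/0.924, HR 3.55, C-indices up to 0.794)
  require those images and are not reproducible here; the pipeline
  reproduces the qualitative orderings on synthetic cohorts instead.
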