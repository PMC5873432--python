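# Methods

This note documents the statistical model behind `covnet`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
cohorts do and do not emulate.

## Data model

A study unit is a triple of plain-text tables: a subject table
(`subject_id`, `age` in years, `sex` ∈ {F, M}), a region table
(`region_id`, `name`, `hemisphere` ∈ {L, R, midline}, `lobe` ∈ {frontal,
parietal, temporal, occipital, limbic, insula, subcortical},
`homologue_id`), and an M×N myelin matrix of mean regional MT values (MT in
percent units, ≈1 in gray matter). The region-table row order is
authoritative everywhere: matrices, graphs and reports index nodes by it,
so permuting file rows never changes a result. The bundled default
parcellation has 114 regions (56 bilateral pairs + 2 midline vermal
structures), the node count of common volumetric gray-matter atlases.

## Confound detrending

Within each analysis unit (an age group, or a sliding window) every region
is residualized by OLS on the shared design
[1, age, age², sex, age×sex]. Age is mean-centered within the unit before
squaring — this changes the reported coefficients but provably not the
residuals, and tames collinearity. Sex is coded F = 0, M = 1 (the coding
is arbitrary for residuals and is echoed in every report). Single-sex
units drop the sex and interaction columns with a warning; any residual
rank deficiency is resolved by greedy column dropping, recorded in the
report. Global MT (unweighted mean over regional means) is *not* removed
as a confound: subtracting it would distort genuine covariance patterns
with no way to estimate the introduced bias.

## Covariance network and connectivity summaries

Edges are across-subject Pearson correlations of detrended regional MT;
self-connections are excluded (zero diagonal). All mean-correlation
summaries — global (all N(N−1)/2 pairs), homologous (the left/right pair
diagonal), within-lobe (both hemispheres pooled) and per-region — use one
estimator: |r| values pass through Fisher's z = atanh|r|, are averaged, and
return via tanh. |r| ≥ 1−10⁻⁷ is clamped before atanh (clamp events are
warned about). Because pooling conventions differ across the literature,
the raw arithmetic mean of |r| is stored alongside every summary. Partial
correlations are out of scope by design: with fewer subjects than regions
they cannot be estimated robustly.

## Thresholding

At sparsity s the cutoff R_k is the empirical s-quantile of the off-
diagonal |C_ij|; an edge exists iff |C_ij| > R_k (strict, applied to the
upper triangle and mirrored so the graph is exactly symmetric). With
distinct magnitudes the edge count is exactly round((1−s)·N(N−1)/2); ties
at R_k can only undershoot the target and are logged. An all-tied matrix
(no achievable sparsity) is a degenerate-data error. The default grid is
0.50–0.90 in steps of 0.02 (21 points): dense enough for stable attribute
estimates, sparse enough to suppress spurious edges.

## Graph attributes

* Clustering C_i = 2·triangles_i/(k_i(k_i−1)), C_i = 0 for degree < 2;
  C = mean over all N nodes (C = 1 iff the graph is complete).
* Characteristic path length L = mean geodesic distance over *connected*
  ordered pairs; the disconnected-pair fraction is reported alongside.
  Excluding infinite distances keeps L finite on fragmented high-sparsity
  graphs and matches common practice in the covariance-network literature;
  an empty graph yields NaN with a flag.
* Global efficiency E_glob = mean of 1/d_ij over all ordered pairs with
  1/∞ = 0; local efficiency E_loc = mean over nodes of E_glob of the
  neighbor-induced subgraph (0 for degree < 2). Degree-0/1 nodes stay in
  the N-denominators.
* Betweenness B_i counts geodesics through i fractionally over equal-length
  alternatives (Freeman/Brandes definition), endpoints excluded, unordered
  pairs. Normalized betweenness b_i = B_i/⟨B⟩ with ⟨B⟩ the mean over all
  N nodes; when ⟨B⟩ = 0 (e.g. a complete graph) all b_i are defined as 0
  with a flag. Hubs are nodes with b_i strictly above 1.5.

Implementation: distances by boolean-matrix BFS; geodesic counts by the
identity that walks of length d(s,t) are exactly the shortest paths, so
σ_st = (A^d(s,t))_st; betweenness from the decomposition
σ_si·σ_it/σ_st on the criterion d(s,i)+d(i,t) = d(s,t). All metrics are
validated against exhaustive brute-force oracles and networkx in the test
suite.

Each attribute's curve over the sparsity grid is reduced to its trapezoid
area (AUC) — the scalar compared between groups. A single-point grid has
AUC defined as 0, with a warning.

## Bootstrap inference

Group statistics are bootstrapped at the subject level: each of n_boot
(default 2000) draws resamples M subjects with replacement (classical
Efron bootstrap, resample size = M), re-fits the confound regression on
the resample, recomputes the correlation matrix and evaluates every
statistic. Re-fitting inside the resample propagates the detrending
uncertainty; resampling precomputed residuals is available but slightly
understates variance (the residuals live in an (M−5)-dimensional space).
Resamples containing a zero-variance region are redrawn (≤10 retries,
counted).

The difference test forms diff_b = A_b − B_b by bootstrap index (the groups
are resampled independently, so index pairing is statistically equivalent
to any pairing), and builds a bias-corrected (BC) percentile CI:
z0 = Φ⁻¹(#{diff < point estimate}/n_boot), endpoints at the
Φ(2z0 + z_{α/2}) and Φ(2z0 + z_{1−α/2}) percentiles. Endpoints use
outward-rounded order statistics rather than interpolation — the
conservative convention for discrete bootstrap distributions, which
matters at small n_boot. Acceleration (BCa) is not estimable from the
difference distribution alone and is not used. A difference is significant
iff the 95 % CI excludes zero. No multiplicity correction is applied
across the many reported statistics; reports carry raw per-comparison
decisions.

Measured operating characteristics (synthetic cohorts, 75/group,
n_boot = 200, homologous-connectivity statistic): type-I error ≈ 4–7 %
at nominal 5 %, power ≈ 1.0 for a planted coupling difference of 0.4.
Near-null mean-|r| statistics (e.g. global connectivity on an uncoupled
cohort) are anti-conservative under any subject bootstrap because folding
|r| converts resampling noise into signal; treat such contrasts with care.

## Targeted attack

Nodes are removed one at a time in descending b_i (ties: higher degree,
then region id), the order computed once on the intact graph — the static
variant matches the procedure of the resilience literature this analysis
follows; a recompute-after-every-removal variant exists behind a flag.
After each removal the largest connected component (LCC) is recomputed
(internally: one reverse union-find pass, linear in edges). Robustness is
the trapezoid area under LCC/N versus fraction-of-nodes-removed — in
[0, 1] and comparable across parcellation sizes. Per-sparsity robustness
values are themselves reduced to an AUC over the grid for the group test.

## Sliding-window trajectories

Subjects are sorted by age (ties by subject id) and windowed with constant
size w (default 73, the young-group size — constant w keeps correlation
estimates unbiased by sample size) and step 1, giving M−w+1 windows whose
"age" is the median member age. Each window is detrended and summarized
exactly like a group, without bootstrapping. Within narrow windows age²
can be near-collinear with age; the detrender's automatic column dropping
applies per window and is logged.

Each series is fitted with polynomials of order 1..max_order (default 6,
the highest order the nodal-centrality trajectories require) on centered
ages. Candidate orders are ranked by the regression AIC
n·ln(RSS/n) + 2(k+1) with k = order+1 coefficients; RSS is floored at
n·var(y)·10⁻¹⁸ so exact fits compare by the parameter penalty rather than
by rounding noise. The selected order is the smallest within ΔAIC ≤ 2 of
the minimum — the standard parsimony convention for nested models, under
which a true cubic is recovered ≥90 % of the time in the calibration
tests (bare arg-min AIC over-selects higher orders ~25 % of the time for
purely combinatorial reasons). Coefficient significance comes from OLS t
tests. Consecutive windows share w−1 subjects, so series values are
strongly autocorrelated; the t tests treat windows as independent and are
therefore descriptive, not confirmatory.

## Synthetic cohorts

The generator plants known structure at realistic magnitudes:

* ages uniform in the configured range; sex assigned by rounded female
  fraction (defaults mirror the study groups: 73 subjects, 35 F, 20–31 y;
  78 subjects, 40 F, 60–71 y);
* per-region mean MT: baseline ≈ 1.0 ± 0.05 (between-region SD), concave
  quadratic in age with per-region peak drawn uniformly in 40–50 y and
  curvature 8·10⁻⁵ MT/y² (≈5 % drop 25 years from the peak — an
  inverted-U lifespan trajectory of gray-matter myelination); additive sex
  effect 0.01 MT and optional age×sex term;
* residuals from unit-variance latent factors scaled by noise_sd
  (default 0.03 MT): one factor per homologous pair with loading √hc, one
  per lobe with loading √lc, unique loading √(1−hc−lc). Planted Pearson
  correlations are therefore hc+lc within a homologous pair, lc within a
  lobe, 0 across lobes; the construction is positive semi-definite by
  construction whenever hc+lc < 1 (violations are a config error).
  Defaults hc = 0.45, lc = 0.15 (young) and hc = 0.60 (old) put homologous
  correlations at 0.60/0.75 and lobe correlations at 0.15 — homologous
  pairs strongest, as observed empirically;
* optional age profiles — a linear slope on hc and an inverted-U profile
  on lc — for planting trajectory trends.

What the generator does **not** emulate: voxel-level noise and
registration error, iron/R2* contamination of MT, non-Gaussian residuals,
long-range (cross-lobe) covariance, regionally heterogeneous aging rates,
and realistic (non-uniform) age distributions. Passing tests therefore
demonstrate that the pipeline recovers the structure this model plants at
these sample sizes — not that real MRI data satisfy the model.

## Numerical conventions and degenerate inputs

* Correlation columns with SD ≤ 10⁻¹⁰ (rounding-level residuals) are a
  degenerate-data error naming the region.
* |r| clamping before atanh at 1−10⁻⁷; counts logged.
* Thresholding on an all-tied matrix, empty correlation lists, windows
  larger than the cohort, single-sex designs, constant ages, and
  degenerate bootstrap difference distributions all raise typed errors or
  warnings rather than propagating NaNs.
* One global seed spawns independent child seeds (numpy SeedSequence) for
  every group and stage; all reports echo config and seeds and serialize
  with sorted keys, so a (config, seed) pair reproduces every output file
  byte for byte.

## Problem sizes used in the test suite

Oracle equivalence runs 200 random graphs with N ≤ 10 against exhaustive
enumeration; recovery tests use single cohorts of n = 400–500; inference
calibration uses 200 replicate two-group experiments (75/group,
n_boot = 200) and 50 replicates for power; the end-to-end run uses the
full study dimensionality (73+78 subjects, 114 regions, 21 sparsity
points, n_boot = 200) — chosen to exercise every statistic, including
per-region centrality and attack robustness, at realistic scale.

## Known limitations

* Binary, unweighted graphs only; no weighted metrics, small-world
  indices, or community structure.
* BC (not BCa) intervals; no multiplicity control.
* Static attack order by default; recomputed centrality available but
  untested against published baselines.
* The sliding-window t tests ignore window overlap (see above).
* Sex is modeled as a binary covariate because the design it reproduces
  recorded it that way.
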