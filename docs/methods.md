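# Methods

This note records the statistical model, the synthetic data-generating
process, the numerical choices and the known limitations of `clpnet`.
It states nothing the test suite or `scripts/acceptance.py` does not
itself compute.

## Cross-lagged panel network estimation

A CLPN over *p* symptoms is estimated one outcome at a time.  For
wave-2 symptom *j* (z-scored within wave, population-sd convention,
divisor *n*):

    minimize over (beta, gamma):
        1/(2n) || z2_j - Z1 beta - C gamma ||^2  +  lambda ||beta||_1

where `Z1` holds the 24 z-scored wave-1 symptoms (penalized) and `C` the
intercept plus covariates (sex; unpenalized by default, since control
variables should not be shrunk away).  Columns of the network matrix
`W` are assembled from the `beta` vectors; the diagonal carries the
autoregressive paths.  Whole-sample fits adjust for sex; gender-specific
networks are fit on the subset with the (then constant) covariate
omitted — subsetting rather than interaction terms, matching the idea of
estimating the networks "separately" per group.

Choices that matter:

* **Standardization before regression.**  Ordinal 0–4 items have very
  different variances (especially the zero-inflated NSSI items); without
  z-scoring the edge weights would not be comparable across items.
  Scores are treated as continuous in the regressions, the standard
  CLPN practice; no ordinal link is modelled.
* **Penalty selection.**  Per outcome, a log-spaced grid of 100 penalty
  values descends from λ_max = max |X'r|/n (the smallest value zeroing
  every penalized coefficient, computed after projecting out the
  unpenalized block) to 1e−4·λ_max.  K = 10-fold cross-validation with
  folds fixed by `cv_seed` (the same folds for every outcome) selects
  λ by the CV-error minimum (`lambda_rule="min"`, the default) or the
  one-standard-error rule (`"one_se"`).  The min rule is deliberately
  liberal: on pure-noise outcomes it retains a few spurious small
  coefficients (about 5–8% of the possible edges; verified to match R's
  `cv.glmnet` `lambda.min` edge-for-edge on shared folds), whereas the
  one-SE rule returns the empty model almost always.  Users who need
  conservative null behaviour should select `one_se`.
* **Solver.**  Cyclic coordinate descent on the Gram system with warm
  starts along the grid (numba-compiled, pure-Python fallback),
  convergence at 1e−7 maximal coefficient change, at most 10,000
  sweeps.  Unpenalized covariates are handled exactly by
  Frisch–Waugh profiling: lasso on the residualized problem, then a
  least-squares refit of the unpenalized block.  Every fit can be
  certified against the KKT stationarity conditions
  (`kkt_residuals`): zeroed coordinates satisfy |gradient| ≤ λ + 1e−6,
  unpenalized coordinates have zero gradient.  λ = 0 reproduces
  ordinary least squares to ~1e−9.
* **Nonzero edge = exactly nonzero coefficient.**  No extra
  thresholding at estimation time; the β > 0.06 display rule is a
  separate reporting step (`threshold_edges`, strict inequality).

## Centrality, bridges, comparison

Expected influence sums *signed* cross-lagged weights (out-EI over a
node's row, in-EI over its column, diagonal excluded), so
symptom-dampening edges count negatively; an absolute-value variant is
available for sensitivity analysis.  Σ out-EI = Σ in-EI holds exactly
for every network.  Bridge edges are nonzero cross-community edges
ranked by |weight| with deterministic lexicographic tie-breaking.
Network comparison reports the Pearson correlation of the vectorized
off-diagonal weights, the mutual overlap percentages of nonzero edge
sets, and the Jaccard index over directed edges; by default an edge is
"shared" only when it is nonzero in both networks *with the same sign*
(direction-only matching is available via `sign_sensitive=False`, since
either reading of "same orientation" is defensible).  A network with no
nonzero edges gets `None` for overlap/Jaccard rather than a fabricated
number.

## Bootstrap edge-weight accuracy

Non-parametric: subjects resampled with replacement to the original n,
the full network re-fit per replicate — by default re-running CV
penalty selection inside every replicate, so the intervals reflect the
whole procedure's variability; a fixed-λ mode exists for speed.
Intervals are symmetric percentile intervals whose endpoints are order
statistics (k = ceil(B·α/2)-th and (B−k+1)-th of B replicate draws), so
99% intervals contain 95% ones by construction.  Replicates that fail
(a zero-variance column in a degenerate resample) are dropped and
counted, and the run aborts when more than 5% fail.  BCa intervals and
case-dropping stability coefficients are out of scope.

Calibration, computed by the acceptance suite on a 6-node sparse linear
truth (effects 0.25–0.4, wave-1 equicorrelation 0.3, n = 300, 200
datasets × 200 replicates): empirical 95% CI coverage of the true
nonzero weights is ≈ 0.93 (per-edge 0.87–0.98).  Coverage sits below
0.95 because lasso point estimates are biased toward zero by roughly
the selected λ; with the penalty re-selected per replicate the
intervals absorb most but not all of that bias.

## Synthetic panel generator

The generator emulates the study design the package targets: n = 884
(403 boys / 481 girls expected), two waves, 24 ordinal 0–4 items.
Wave-1 latents are multivariate normal with block correlations (0.4
within NSSI, 0.5 within depression and within anxiety, 0.3 between
depression and anxiety, 0.15 between NSSI and the affect blocks —
free config parameters whose defaults reproduce the sign pattern of
scale-level correlations typical of such cohorts).  Discretization uses
per-node increasing cut-points; NSSI items share a high first cut-point
solved numerically (one-factor integral + Brent root) so that
P(any of 12 items > 0) = 0.233, the any-NSSI prevalence anchor;
affect items use cut-points (0.2, 1.0, 1.7, 2.4), giving right-skewed
items with mean ≈ 0.6.  Zero inflation is produced by the thresholds
alone, not a separate hurdle process.  Wave 2 follows
`eta2 = B' s1 + eps` (noise sd 1.0) and is discretized the same way.

**Drive scale.**  By default `s1` is the z-scored wave-1 *ordinal*
score vector — the same scale the estimator regresses on — so the
ground-truth matrix `B` is the estimand of the fitted regressions and
parameter recovery is well defined.  A `"latent"` drive mode feeds the
wave-1 latents directly; in that mode discretization attenuates the
observed-scale effects drastically (for a 3.5%-prevalence NSSI item a
latent coefficient of −0.57 yields an observed-scale estimand of only
≈ −0.07), which makes latent drive useful for structural checks but
meaningless for weight recovery.  This is a deliberate design
resolution: a simulator whose truth is not estimable on the analysis
scale cannot validate an estimator.

**What recovery can and cannot show.**  Even on the observed drive
scale the bounded 0–4 outcome floors large effects: an engaging subject
on a rare NSSI item sits ≈ 5 SD above the item mean, and a −0.57
coefficient would demand an outcome drop of ≈ 3 SD where the ordinal
floor allows ≈ 0.7.  Measured at n = 40,000, the estimands of the three
strong boys' bridges (−0.57, −0.52, −0.49) compress to (−0.144,
−0.133, −0.131).  Consequently the fitted networks recover *signs*
reliably (60/60 strong-edge sign matches over 10 seeds at n = 884 per
group) and the qualitative bridge pattern, but not the magnitudes, and
the *ordering* among the three nearly-tied N9 edges is resolved in only
about 7 of 10 seeds — a power limit of the design, not of the
estimator.  Passing tests therefore demonstrate sign/structure
recovery under realistic marginals; they do not certify magnitude
recovery on bounded ordinal scales, and real questionnaire data carry
the same limitation.

Seeding: group assignment, wave-1 latents and wave-2 noise use separate
child streams spawned from `SeedSequence(seed)`, with subjects processed
in fixed order, so any stage is independently reproducible and
regeneration is byte-identical.  A separate linear-Gaussian generator
(`simulate_linear_panel`) produces continuous panels with unit-variance
wave-2 columns, used where the estimand must equal `B` exactly
(estimator calibration, bootstrap coverage).

## Reporting conventions

Sample-accounting percentages are *truncated* (not rounded) to two
decimals — 403/884 → 45.58 — matching the convention of the cohort
reports this mirrors.  Panels are wide CSVs
(`subject_id, gender, t1_<node>, ..., t2_<node>`; 0 = boy, 1 = girl);
rows with missing or out-of-range scores are flagged and excluded
listwise, never silently dropped; fractional scores and unknown gender
codes are hard errors.  Scale of problem sizes in the test suite:
recovery runs use n = 884 per group and 10 seeds; the null-network
check n = 500 and 20 seeds; bootstrap coverage 200 × 200 at n = 300 —
sizes chosen to estimate each property with useful precision on a
single CPU.

## Known limitations

* Two waves, two groups, listwise deletion only; no attrition model,
  no measurement-error model, no within-wave (contemporaneous)
  networks, no multi-wave extensions.
* Ordinal items are regressed as continuous; no ordinal-link variant.
* The min-rule CV default trades null sparsity for sensitivity; the
  one-SE rule is the conservative alternative.
* Percentile (not BCa) bootstrap intervals; lasso shrinkage bias is
  only partly absorbed.
* The generator's autoregressive diagonals are homogeneous per group;
  per-item heterogeneity of autoregression is not emulated.
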