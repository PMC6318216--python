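# Methods

## The model

Tree-component dry biomass W (Mg) is modelled as directly proportional to
stem volume V (m³):

    Ŵ = BCEF · V

The proportionality constant — the biomass conversion and expansion factor
(BCEF, Mg m⁻³) — is the slope of a regression through the origin (RTO).
Forest-inventory practice usually does not estimate this slope by least
squares; it takes a ratio of observed biomass to volume.  The package
implements both conventions so they can be compared on equal terms:

| method | slope | leverage H_ii |
|---|---|---|
| `ratio_mean_of_ratios` | (1/n) Σ Wᵢ/Vᵢ | 1/n |
| `ratio_ratio_of_means` | ΣW / ΣV | Vᵢ/ΣV |
| `ls_rto` | Σ WᵢVᵢ / Σ Vᵢ² | Vᵢ²/ΣV² |
| `glm_rto` | Gamma-GLM ML slope, identity link | wᵢVᵢ²/Σ wⱼVⱼ², wᵢ = 1/μᵢ² |

The three non-GLM methods are one-parameter linear smoothers, and each is a
weighted least-squares RTO in disguise: weights 1/Vᵢ² give the mean of
ratios, weights 1/Vᵢ give the ratio of means, unit weights give `ls_rto`.
Which one is efficient therefore depends entirely on how the residual
variance scales with volume (Var ∝ V², Var ∝ V, Var constant respectively).
The comparison machinery makes no efficiency assumption; it scores all
methods empirically.

A useful algebraic fact the tests pin down: the Gamma GLM with identity
link has IRLS weights 1/μᵢ² = 1/(b·Vᵢ)², so its ML slope *is* the mean of
per-tree ratios.  When the normality gate (below) switches a fit to the
GLM, its point estimate coincides with `ratio_mean_of_ratios`; only the
standard error changes, since it comes from the Gamma likelihood.

## Is forcing the origin admissible?

Zero volume implies zero biomass, but that alone does not license RTO: if
the true intercept is nonzero, the RTO slope is badly biased.
`intercept_zero_test` fits the unconstrained line W = α + βV + ε by OLS and
tests H0: α = 0 with t = α̂/SE(α̂) on n − 2 degrees of freedom.  The test is
calibrated (size 3–7% at the 5% level in the seeded null simulations) and
detects an intercept of twice the noise sd with essentially full power at
n = 100.

## Normality gate

`BcefModel.fit_auto` fits the LS RTO first and runs Shapiro–Wilk on its
residuals; if the test rejects at `alpha_level` (default 0.05) and all
biomass values are positive, the fit is redone as a Gamma GLM.  The gate
can instead be run on the residuals of the unconstrained two-parameter OLS
fit (`gate_on="ols"`); the RTO residuals are the default because they are
the residuals of the model actually being fitted.  An exact (zero-residual)
fit bypasses the gate: there is no dispersion to diagnose.  The Gamma
family with identity link was chosen because biomass is positive and
right-skewed while the identity link preserves the proportional reading of
the slope; family and link are configurable.

## Scoring

*Accuracy* (in-sample):

- **AIC** under the full Gaussian likelihood, n·ln(2πσ̂²) + n + 2k with
  σ̂² = RSS/n and k = 2 (slope + variance) for every method.  The ratio
  estimators are not likelihood fits, so their AIC is defined as the
  Gaussian likelihood evaluated at their slope — both methods then carry
  identical penalties and differ only through RSS.  A perfect fit has no
  finite AIC; the score card reports −inf rather than failing so noiseless
  data can be processed end to end.
- **SE%**: 100·SE/estimate.  The mean-of-ratios SE is sd(ratios)/√n; the
  ratio-of-means SE is the classical ratio-estimator variance
  √[Σ(Wᵢ−RVᵢ)²/((n−1)·n·V̄²)]; the RTO SE is √(σ̂²/ΣV²) with σ̂² = RSS/(n−1)
  (one fitted mean parameter).
- **CVr**: 100·√(RSS/(n−dof))/mean(W), dof = 1.
- **Furnival index**: RMSE divided by the geometric mean of the response
  transform derivative; for the untransformed response used throughout this
  package it reduces to the residual RMSE (Mg).

*Ability* (out-of-sample):

- **MEP** = (1/n) Σ eᵢ²/(1 − Hᵢᵢ)², using each estimator's own hat
  diagonal.  For a linear smoother this equals PRESS/n, the mean squared
  leave-one-out prediction error, which the tests verify against explicit
  n-refit leave-one-out for all three linear methods at 1e-9 relative
  tolerance.  Using each method's own smoother (rather than imposing the
  LS hat on all) is what makes that identity hold uniformly.
- **MPE**: K-fold cross-validation (K = 10, seeded shuffle, near-equal
  folds), pooling all n held-out errors into a root mean squared
  prediction error; mean absolute error is available via `cost="mae"`.
  Samples smaller than K degrade to leave-one-out.

Confidence intervals for every method use a t critical value on **n − 2**
degrees of freedom.  For the one-parameter RTO, n − 1 would be orthodox;
n − 2 is kept uniformly so ratio and LS intervals are directly comparable,
at the price of slightly conservative RTO coverage (measured ≈ 95.4% at
n = 30 for a nominal 95%).

## Comparison summaries

For each (species, component) pair the relative reduction of a metric m
going from ratio to LS is 100·(m_ratio − m_LS)/|m_ratio|; the absolute
value keeps the sign meaningful when AIC is negative.  Pairs where the
ratio metric is 0 but the LS metric is not are excluded as undefined (and
counted); both-zero pairs count as 0%.  Negative reductions (ratio better)
are reported, never clipped; summaries give min/max over all pairs and over
the positive pairs alone.  The biomass-difference summary converts the
BCEF gap into Mg per 100 m³ of stem volume and reports both the largest
gap's percentage and the overall percentage maximum (foliage BCEFs are two
orders of magnitude smaller than stem BCEFs, so their percentage gaps can
be large while their absolute gaps are negligible).

The package ships a transcribed published comparison table (four mopane and
miombo timber species from Mozambique, five components, both methods,
40 rows) under `bcef/data/reference_bcef_metrics.csv`; the summary
arithmetic above applied to it yields the headline numbers in the README.

## Field-measurement reduction

Stem volume comes either directly or from the sectional (mid-area) formula
over five equal-length segments, V = Σ (π/4)(dᵢ/100)²·Lᵢ, with dᵢ measured
at segment midpoints and the stump excluded.  The whole-stem form with end
corrections is *not* used; the plain sectional mid-area form is assumed.
Segment, branch and foliage dry masses scale the field fresh mass by the
disc oven-dry/fresh ratio.  Crown (branches + foliage) and aboveground
biomass (stem + crown) are always derived, so additivity is structural.
Trees sampled leaf-off carry foliage mass 0 with a flag rather than a
missing value, keeping additivity testable.  Masses are kg at the file
boundary and Mg everywhere downstream, so fitted BCEFs are in Mg m⁻³.

## Synthetic populations

The generator draws stem volumes from a lognormal truncated to
[v_min, v_max] (natural stands are strongly right-skewed in volume) and
builds W_c = BCEF_c·V + shift + noise for stem, branches and foliage, with
crown and AGB derived.  Noise models: homoscedastic Gaussian; Gaussian with
sd ∝ V^γ; multiplicative lognormal (median-unbiased).  Negative draws are
resampled, never clipped — clipping would put a point mass at zero mass —
and the resample count is recorded in `Dataset.meta`.

`reference_scenario()` emulates a published 75-tree destructive-sampling
study: sample sizes 17, 24, 15, 19; per-species volume ranges and means
matched by solving the truncated-lognormal meanlog so the truncated mean
hits the published mean, with sdlog = (ln v_max − ln v_min)/3 (the
published min/max are sample extremes of n ≈ 15–24 draws, which sit near
±1.5 sd); true BCEFs set to the published least-squares estimates; noise
homoscedastic Gaussian with sd equal to 30% of the mean component biomass.
Homoscedasticity is the error structure that study's own diagnostics
support (residuals of the unweighted fit found normal), and it reproduces
the qualitative signature of the published tables: per-tree ratios of small
trees scatter wildly, ratio-based SEs are several times the LS ones, and
the LS fit out-predicts the ratio fit (lower MEP and MPE) in most
species × component cells.  DBH and height are filled by a crude monotone
log-linear map of volume onto the published dimension ranges — schema
completeness only, never used in fitting.

What the generator does *not* emulate: the true joint distribution of
(V, W) in any real stand (only marginal ranges and a proportional mean are
matched), measurement error in volume itself, between-tree correlation of
component masses, or any DBH–height allometry.  Passing tests on synthetic
populations therefore demonstrate the estimators' statistical behaviour
under the stated noise models, not field accuracy for any particular
species.

## Numerical choices and degenerate inputs

- Slopes and hat diagonals use closed forms; no iterative solver is
  involved outside the GLM (statsmodels IRLS, max 200 iterations,
  convergence failure raises with the iteration trace).
- Exact proportional data: every estimator returns the exact slope with
  SE 0; the CI degenerates to a point; MEP/MPE are 0; AIC is −inf in the
  score card and an error in the raw `aic_gaussian`.
- Ratio estimators require all V > 0; the LS RTO only requires ΣV² > 0.
  W = 0 is allowed everywhere except the Gamma GLM.
- Fits need n ≥ 2 (n ≥ 3 for anything involving a t quantile or the gate);
  subsets smaller than that are flagged in comparison tables, not dropped.
- Equal-length segment check uses a 1e-6 relative tolerance; the
  degenerate-residual check in the intercept test uses RSS ≤ 1e-20·ΣW².
- K-fold partition: seeded permutation + `array_split`, so fold sizes
  differ by at most one; the pooled cost is invariant to fold labelling.

## Known limitations

- The published Furnival-index values in the transcribed reference table
  do not follow from FI = RMSE and the published summary statistics under
  any convention we could reconstruct; FI is therefore implemented in its
  standard form and excluded from the headline summaries.
- Printed SE% conventions in the source tables are likewise not fully
  reconstructible (the mean-of-ratios SE% is mathematically bounded by
  100·√(n−1)/√n for positive data, below some printed values); both ratio
  variants are provided and the choice is a config switch.
- The GLM standard error is asymptotic; at the n ≈ 15–25 typical of
  destructive samples it is optimistic.
- Problem sizes in tests and the acceptance script (2000 replicates at
  n = 30 for coverage, 1000 at n = 50 for test size, one 75-tree scenario
  per seed for the direction check) were chosen to make the Monte Carlo
  error a small fraction of the tolerance bands they are checked against.
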