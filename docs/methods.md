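# Methods

## Scope and model

kmcut performs univariate and multivariate survival analysis on a
delimited sample table: per-sample follow-up time, a 0/1 event flag, up
to three categorical filter columns, and any number of continuous or
binary marker columns. The statistical core is standard right-censored
survival methodology:

* **Kaplan-Meier product-limit estimator.** For distinct event times
  t₁ < t₂ < … with dᵢ events among nᵢ at risk,
  Ŝ(t) = ∏_{tᵢ ≤ t} (1 − dᵢ/nᵢ). Censored observations leave the risk
  set after their last follow-up. Confidence bands use the Greenwood
  variance on log Ŝ: Var(log Ŝ) = Σ dᵢ/(nᵢ(nᵢ−dᵢ)), with 95% bands
  exp(log Ŝ ± 1.96·se). Median survival is the smallest event time with
  Ŝ ≤ 0.5 (boundary inclusive); when the curve never reaches 0.5 the
  upper-quartile survival (Ŝ ≤ 0.75) is reported instead, and flagged.
* **Log-rank (Cox–Mantel) test.** Two-group comparison with the pooled
  hypergeometric variance at each event time; χ² on 1 df.
* **Cox proportional-hazards regression.** Partial likelihood maximized
  by Newton–Raphson with the Efron correction for tied event times
  (Breslow selectable). Start β = 0, covariates mean-centered,
  step-halving on any likelihood decrease, convergence at max|Δβ| <
  1e-9 or relative log-likelihood change < 1e-9, 50 iterations maximum.
  Standard errors come from the inverse observed information; per-term
  Wald p-values and a likelihood-ratio global p are reported, CI level
  fixed at 95%. A coefficient exceeding 10 per covariate SD is treated
  as a monotone likelihood (perfect separation / all events in one
  cohort) and raises a non-convergence error carrying the diverging
  direction; the pipeline level reports such fits as an infinite HR
  while keeping the curves and the log-rank test. Cohorts under 40
  samples trigger a small-sample warning, because the Cox asymptotics
  are unreliable there.
* **HR inversion.** A hazard ratio is relative to a baseline, so 0.5
  for high-vs-low equals 2 for low-vs-high. The optional inversion maps
  (β, HR, CI) to (−β, 1/HR, [1/CI₊, 1/CI₋]) and swaps the cohort
  labels; p-values are invariant.
* **Proportional-hazards diagnostic.** Grambsch–Therneau test on scaled
  Schoenfeld residuals. Residuals at each event are x − x̄(t, β̂) (with
  Efron ties, the mean of the d Efron-weighted risk-set means). The
  statistic correlates residuals with a transform g(t) of event time;
  the default is the left-continuous Kaplan-Meier transform
  g = 1 − Ŝ(t⁻), identity selectable. Per-covariate χ² uses the fit's
  covariance diagonal; the global χ² pools all covariates. Violation is
  flagged at p < 0.05.

## Cutoff selection

Continuous markers are dichotomized at value ≤ cutoff → "low" (one
boundary convention applied everywhere, including median
stratification). Strategies:

* fixed quantile (median, lower/upper quartile; type-7
  linear-interpolation quantiles throughout);
* trichotomization at the 1/3 and 2/3 quantiles with the middle tertile
  omitted (omitted count reported);
* **best-cutoff scan**: every distinct observed marker value inside
  [Q1, Q3] is a candidate (any other threshold dichotomizes identically
  to some observed value, and the quartile bounds guarantee each cohort
  holds at least a quarter of the samples). At each candidate a
  univariate Cox model of the high-vs-low indicator is fitted; the Wald
  p and the HR inverted to ≥ 1 are recorded, and the candidate with the
  smallest p wins. Exact p ties (relative tolerance 1e-9) are broken by
  the largest HR and flagged ambiguous; a wider ambiguity window
  (p ≤ k·min p) is available but off by default since no principled k
  exists. Candidates whose fit fails (e.g. perfect separation) are kept
  in the scan output as NaN rather than aborting the scan.

Because the scan tests many hypotheses on one marker,
Benjamini–Hochberg adjusted q-values are computed across the scan's own
p vector (scipy's step-up implementation) and attached to every
candidate; the selected cutoff's q is the headline FDR figure. The
adjustment is conservative here — neighbouring cutoffs move only a few
samples between cohorts, so the tests are strongly dependent — which is
the safe direction. In batch mode a second BH pass across markers'
p-values is available.

## Combining markers

All combination modes produce an ordinary derived column that flows
through cutoff selection and survival analysis unchanged:

* signature mean: Σ wᵢsᵢxᵢ / Σ wᵢ with sᵢ = −1 for inverted members;
  weights must be nonnegative (sign changes go through the invert flag,
  keeping the two mechanisms distinct) and raw values are averaged by
  default — an optional z-score flag standardizes members first for
  panels on incompatible scales;
* ratio of two markers (zero denominators are an error listing the
  offending samples);
* median stratification: split the cohort at one marker's median
  (≤ median → low arm) and analyse another marker inside one arm; arms
  under 4 samples are rejected;
* batch mode: the identical univariate analysis per marker, failures
  isolated per marker.

Pearson and Spearman correlations between markers use scipy with
two-sided p-values.

## Multivariate models

Complete-case analysis: only samples with every selected variable
observed enter, the excluded count is reported, and fewer than 2
remaining events is an error. Markers enter continuously by default;
dichotomization is opt-in and the cutoff is then computed within the
complete-case cohort, so the model and the cutoff see the same samples.
Categorical variables (≤ 10 levels) are dummy-coded against the
lexicographically first level (overridable). Rank deficiency of the
centered design matrix is detected before fitting and reported with the
aliased columns. No stepwise selection, strata terms, time-varying
covariates or interactions.

## Input contract

Tables are tab-, semicolon- or comma-separated (preference order
tab > semicolon > comma when consistent); limits are 100 columns, 8000
data rows, 3 filters, 10 distinct values per filter, events coded 0/1,
headers restricted to English letters, digits, spaces, underscores,
colons, round brackets and exclamation marks. Column roles are
recognized automatically: the first numeric column whose header
contains "time" (else the first numeric non-binary column, with a
warning) is the survival time; a header containing "event"/"status"
(else the first strictly binary column after the time column, with a
warning) is the event; the first non-numeric column is the sample id;
"filter" headers and small text categoricals become filters. Rows with
missing time or event are dropped with a logged count; marker columns
with missing cells are demoted to unusable rather than imputed — only
full columns are acceptable as variables. Decimal separator is "."
regardless of dialect. Duplicate sample ids warn; duplicate headers
are an error.

## Synthetic cohorts

The generator emulates expression-like data: markers are log-normal
(log-mean 7, log-SD 1, values around 10³) with an optional common
marker-marker correlation; event times follow an exponential or Weibull
baseline hazard scaled per sample by exp(Σ log(HRᵢ)·zᵢ) where zᵢ is the
standardized log-marker, so "true HR" means hazard ratio per SD of log
expression. Censoring is an independent Uniform(0, c) time with c
calibrated by bisection to hit the requested censoring fraction (±5%
enforced). One seeded PCG64 stream makes every dataset bit-reproducible.
What the generator does not emulate: covariate-dependent censoring,
cohort heterogeneity or batch structure, non-log-normal marker
distributions, and real clinical filter columns — so passing tests
demonstrate correctness of the estimators and pipeline under the
model's own assumptions, not robustness to messy real-world cohorts.

## Problem sizes and numerical choices

The simulation suites use 500 replicates for coverage and calibration
claims (binomial SE ≈ 1% at a 5% rate), cohorts of n = 2000 for
parameter recovery, n = 200 for the null cutoff-scan study and n = 500
(Weibull shapes 0.5 vs 2) for the power study — sizes at which the
asymptotic claims under test are expected to hold while the full suite
completes in a few minutes. Calibration assertions use bands fixed in
advance: type-I error within [2%, 9%] at α = 0.05, CI coverage within
[92%, 98%], null scan min-q rate below 8%.

Ties in the scan's argmin are resolved by HR as described; ties in
marker values at a quantile boundary follow the ≤ convention
deterministically. Events at t = 0 are kept with the full risk set;
negative times are a validation error. The log-sum-exp guard (shifting
the linear predictor by its maximum) keeps partial-likelihood
evaluation finite for large coefficients.

## Known limitations

* The best-cutoff scan's selected p-value is biased low by construction
  (minimum over candidates); the attached BH q mitigates but does not
  remove selection optimism — an independent validation cohort does.
* The Grambsch–Therneau statistic here uses the classic average-
  information approximation; implementations that re-estimate the
  information per event time (e.g. newer R releases) give slightly
  different χ² values with the same operating characteristics.
* No generalized log-rank variant for very small samples: below 40
  samples the package warns and proceeds.
* Parametric survival models, competing risks, stratified Cox and
  time-varying effects are out of scope.
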