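# Methods

## Scope and data model

`pgsrisk` estimates absolute disease risk by polygenic score (PGS) stratum
for a population described by GBD-style rate tables: incidence rate per
person-year, point prevalence, cause-specific and all-cause mortality per
(location, sex, 5-year age group) on [0, 80), with optional 95% uncertainty
bounds per measure.  Cohort inputs are individual-level survival records
(study label, sex, PGS, status ∈ {disease, other-death, censored}, exit
age).  The PGS is standardized to mean 0, variance 1 (unbiased variance)
within each study before any model is fitted.

## Survival models

All association models are Cox proportional-hazards fits with **age as the
timescale**: follow-up starts at birth and ends at the first of disease
onset, death from another cause, end of records, or age 80.  Fitting uses
an in-package Newton–Raphson maximizer of the partial likelihood with the
**Efron tie correction** and support for **left truncation** (delayed
entry), vectorized over risk sets with suffix cumulative sums.  It is
validated in the test suite against brute-force partial-likelihood
maximization on toy data and against lifelines on larger cohorts (agreement
to ≤1e-6 in coefficients and standard errors, including delayed entry and
tied event times).

The battery per study:

* **full** — per-SD log HR; a male indicator is included as a covariate in
  mixed-sex fits (sexes are otherwise stratified, never adjusted, in
  per-sex fits).  Additional technical covariates (principal components,
  batch) pass through by column name; the synthetic tests run without them.
* **by sex** — the same model within each sex.
* **interaction** — PGS + sex + PGS×sex; two-sided Wald test on the
  interaction coefficient.
* **onset-age quartiles** — boundaries are per-study onset-age quartiles
  (linear-interpolation/type-7 quantiles) averaged arithmetically across
  studies.  Within interval (L, U]: onset at or before L excludes the
  individual; everyone else enters at L (left truncation) and is censored
  at U; onset inside is the event.  Intervals are half-open on the *left*
  because an event exactly at the entry age would have an empty risk set
  under left truncation — a boundary onset therefore belongs to the
  interval it closes.  Quartile case counts partition the total case count.
* **PGS percentile groups** — default grouping <20 / 20–40 / 40–60
  (reference) / 60–80 / 80–90 / 90–95 / >95.  Percentile of rank r among n
  is 100·(r − 0.5)/n (mid-rank, average ranks for ties), computed within
  study; groups are [lower, upper) with the top group closed.  Group fits
  use categorical coding against the reference and compose with the sex and
  age-interval restrictions.

## Meta-analysis and model selection

Per-stratum estimates are pooled by fixed-effects inverse-variance
meta-analysis (weights 1/se²; pooled SE (Σw)^(−1/2)); a study enters a
stratification scheme only if it converged in every stratum of that scheme
(dropped studies are logged).  Heterogeneity is Cochran's Q against
chi-square with k−1 df.

Age trends are summarized by weighted linear regression of the four
quartile log HRs on the **median onset age within each quartile** (weights
1/se²).  The coefficient covariance is the fixed-scale (X′WX)^(−1) —
appropriate because the weights are known sampling variances; with exactly
two converged quartiles this reduces to exact interpolation with propagated
errors, so no special 2-point fallback is needed.  Slope equality between
sexes is a two-sided z-test with summed variances (the sex strata are
disjoint, hence independent).

The model family is chosen deterministically: **sex** if the pooled
interaction p < α; **age** if the quartile Q p < α; **age-and-sex** if both
hold, or if Q is significant in exactly one sex while not overall, or if
the sex slopes differ at the nominal 0.05; otherwise **full**.
α defaults to 0.05/18 (Bonferroni over 18 diseases) and is configurable;
missing tests count as non-significant and are recorded in the choice
ledger.

## Life table and recalibration

For bin [m, m+5): hazard = incidence/(1 − prevalence);
survival_k = exp(−5·Σ_{m<k}(other-cause mortality + hazard)) with
survival_0 = 1 (the 5 converts per-year rates to 5-year bins);
risk_k = 1 − exp(−5·hazard_k); cumulative incidence is the running sum of
survival_k·risk_k over the 16 bins, reported at boundaries {0, 5, …, 80}.
The within-bin risk deliberately ignores competition with death *inside*
the bin; the resulting discretization bias against the exact continuous
process is ~0.009 absolute at age 80 under the default study conditions and
is covered by the 0.02 consistency tolerance in the tests.

Population incidence is split across PGS groups by the mixture constraint
I_0 = n·I/(n_0 + Σ HR_i·n_i), I_i = I_0·HR_i, which conserves the
population incidence exactly (verified to 1e-12).  Group hazards use the
**population** prevalence for every stratum — a deliberate simplification,
since group-specific prevalence is not available from summary tables — and all strata share the population's other-cause
mortality.  Age-varying HRs are evaluated at the bin **midpoint**
(configurable to the lower bound) and held constant at the nearest fitted
value outside the onset-age range of the quartile fits.  Under an
age-specific family the trend is fitted per PGS group on that group's
quartile HRs; a per-SD rescaling is not applied.  When several studies
share a country the group HRs are meta-analyzed before curves are computed.

An annual sub-grid evaluation uses the constant-hazard closed form within
each bin, CI(a) = CI(m) + survival_m·(1 − exp(−h_m·(a − m))), and
reproduces the 5-year values at boundaries to 1e-12.

## Bootstrap

Parametric, B = 1000 by default (the tests and demo use 200 to keep
runtimes in seconds).  Per replicate: incidence and mortalities are redrawn
log-normally with SD = (log UI upper − log UI lower)/(2·1.96); prevalence
on the logit scale (zero prevalence stays zero); log HRs independently
normal with their SEs (the joint covariance across strata is not available
from summary tables — a documented limitation); age-trend (slope,
intercept) from their joint normal with the WLS covariance.  Two trend
modes exist: sampling the fitted coefficients (default) or re-perturbing
the quartile HRs and refitting the regression inside each replicate.
Bands are pointwise percentiles (2.5/97.5); scalar functionals (crossing
ages) use the same machinery, count "not reached" replicates and flag the
interval unreliable beyond 50%.

## Screening

The threshold is the population curve's value at the index age, evaluated
on the annual sub-grid; crossing ages are solved exactly within the bin
(no curve interpolation), so crossing_age(population, CI(index)) returns
the index age identically and sub-annual ages are faithful to the
piecewise-constant model.  Multi-study averages of crossing ages are
unweighted arithmetic means.

## Synthetic study conditions

The generator draws PGS ~ N(0,1) (sex independent of PGS), piecewise-
constant baseline disease hazard and other-cause mortality, and individual
disease hazard h0(a)·exp(logHR(a, sex)·PGS) with
logHR(a, sex) = β0 + β_sex·1[male] + β_age·(a − 40) + study offset.
The linear-in-age log HR is a testing assumption (the observed attenuation
is approximately linear), not a biological claim.  Event ages are sampled
by exact inversion of the cumulative hazard within segments (the integrand
is exponential in age), so there is no discretization error in the
simulator itself.  Default conditions emulate a common adult-onset disease:
hazards rising from 1e-5/yr in childhood to 0.013/yr in the late 70s
(lifetime risk ≈ 23%), a Western-European mortality schedule, per-SD HR
exp(0.3) ≈ 1.35, administrative censoring at 80.  Derived rate tables are
the analytic consequence of the same process (Gauss–Hermite quadrature over
the PGS, 61 nodes; Gauss–Legendre within age bins), with synthetic 95%
bounds at 5% relative SE on the log/logit scale.

What the generator does *not* emulate: genotype-level structure, PGS
estimation error, ancestry effects, registry under-ascertainment,
disease-dependent mortality, and non-proportional hazards beyond the
linear age trend.  Passing tests therefore demonstrate the correctness of
the estimation and calibration machinery under the stated generative model,
not the clinical validity of any particular PGS.

## Problem sizes in the tests

Replicate-based checks use cohort sizes chosen to make the relevant
standard errors small relative to the effects being detected: 200,000 for
simulator/life-table consistency and model-family recovery (per-SD SE
≈ 0.007, interaction SE ≈ 0.013), 100,000 × 20 replicates for parameter
recovery and CI coverage, 50,000 × 20 for the sign-only comparison of
constant-HR vs age-aware screening ages (effect ≈ 3.4 years vs replicate
SD ≈ 0.5 years), and B = 200 bootstrap replicates for band coverage.

## Known limitations

* Group HRs are perturbed independently in the bootstrap (no cross-stratum
  covariance).
* The life table inherits the printed 5-year discretization, including the
  within-bin treatment of competing death described above.
* The reference-prevalence simplification above slightly misstates group
  hazards when prevalence is large and HRs are extreme.
* Fixed-effects pooling only; between-study heterogeneity is tested, not
  modelled (no random-effects option).
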