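# pgsrisk

**Country-, age- and sex-specific cumulative disease incidence stratified by
polygenic score.**

Polygenic scores (PGS) summarize common-variant genetic liability to complex
disease.  Biobank studies report their effect as a *relative* hazard ratio
(HR) per standard deviation, but clinical decisions — who should be screened,
and from what age — need *absolute* risk in a specific population, accounting
for the competing risk of death and for the fact that PGS effects often
differ between sexes and attenuate with age.  `pgsrisk` implements a complete
pipeline for turning cohort-level PGS associations plus routinely published
population rates (GBD-style incidence, prevalence and mortality per sex and
5-year age group) into PGS-stratum-specific cumulative incidence curves,
bootstrap confidence bands and risk-based screening ages.  It is aimed at
statistical geneticists and genetic epidemiologists, and ships a synthetic
data generator with known ground truth so every stage is testable without
access to individual-level biobank data.

## The model

**Associations.** Cox proportional-hazards regression with age as the
timescale (follow-up from birth; exit at disease onset, death from another
cause, end of records or age 80).  Per study, the battery comprises the
full-sample fit, per-sex fits, a PGS×sex interaction model, fits within
onset-age quartile intervals (delayed entry at the interval start, censoring
at its end, exclusion of prior cases), and categorical PGS-percentile-group
fits against the 40–60% reference group.  Studies are pooled by
fixed-effects (inverse-variance) meta-analysis; heterogeneity uses
Cochran's Q.  A deterministic rule set picks the model family per disease
(full / sex / age / age-and-sex) at a Bonferroni-corrected threshold
α = 0.05/18, with age trends summarized by weighted linear regression of
quartile log HRs on median onset age.

**Absolute risk.**  For each sex and 5-year age group [m, m+5) with
population incidence I, point prevalence p, and mortality rates:

    hazard_[m,m+5)   = I / (1 − p)
    survival_k       = exp(−5 · Σ_{m<k} (mortality_m + hazard_m)),  survival_0 = 1
    risk_k           = 1 − exp(−5 · hazard_k)
    CI(A)            = Σ_{k<A} survival_k · risk_k

where `mortality` is other-cause mortality (all-cause minus cause-specific).
Population incidence is redistributed across PGS groups by the mixture
constraint — the reference-group incidence is

    I_0 = n·I / (n_0 + Σ_i HR_i·n_i),      I_i = I_0 · HR_i

so the proportion-weighted group incidences reproduce the population
incidence exactly at every age.  Group HRs may be constant, sex-specific, or
age-varying (the fitted trend, evaluated at bin midpoints, held constant
outside the fitted onset-age range).  Each group's curve then follows the
life table with shared other-cause mortality.

**Uncertainty and screening.** A parametric bootstrap redraws baseline rates
(log scale, SD from the 95% UI), prevalence (logit scale), log HRs (their
SEs) and trend coefficients (WLS covariance), recomputing curves for
pointwise percentile bands.  The screening threshold is the population's
cumulative incidence at a guideline index age (e.g. 45 for type 2 diabetes,
50 for breast cancer); each stratum's crossing age is solved exactly within
its 5-year bin from the constant-hazard closed form, with a "not reached by
80" sentinel.

## Worked example

```python
from pgsrisk import PgsIncidenceModel, default_config

cfg = default_config(n_individuals=50_000, seed=7)   # T2D-like conditions
res = PgsIncidenceModel.from_simulation(cfg).fit()
print(res.summary())
print(res.screening(45.0, sex="female").table.round(2))
```

prints (abridged):

```
Per-SD log HR (fixed-effects meta-analysis)
  pooled    0.2950  (se 0.0095,  HR 1.343,  k=1)
...
Cumulative incidence at 80 by stratum
  female: population=0.233  <20=0.161  ...  >95=0.387

   stratum  crossing_age  diff_vs_index
population         45.00           0.00
       <20         49.09           4.09
       ...
       >95         39.17          -5.83
```

The generator's true per-SD log HR is 0.30; the fit recovers 0.295 (SE
0.0095).  Lifetime (age-80) risk rises from 16% in the bottom PGS quintile
to 39% in the top 5%, and the top 5% reach the population's age-45 risk
5.8 years early while the bottom quintile reach it 4.1 years late — the
quantities that drive risk-stratified screening proposals.

A CLI wraps the same pipeline:

```bash
pgsrisk pipeline --config examples/demo.yaml --out-dir out/
```

writing cohorts, rate tables, HR estimates, curves with bands, a screening
report and a checksummed manifest.

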