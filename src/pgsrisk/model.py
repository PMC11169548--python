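"""Model/Results facade over the full PGS risk-stratification pipeline.

:class:`PgsIncidenceModel` is built from one or more biobank-style cohorts
plus a GBD-style population rate table; ``fit()`` runs the association
battery (full, sex-stratified, onset-age-quartile and PGS-group Cox models
per study), pools the studies by fixed-effects meta-analysis, applies the
deterministic model-selection rules, recalibrates the population incidence
across PGS strata and returns a :class:`PgsIncidenceResults` carrying the
estimates, their uncertainties, the per-stratum cumulative-incidence curves
and the screening-age machinery.

Typical use::

    cfg = default_config(beta0=0.3, seed=7)
    model = PgsIncidenceModel.from_simulation(cfg)
    res = model.fit()
    print(res.summary())
    curves = res.curves["female"]
    report = res.screening(index_age=45.0, sex="female")
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibrate import (POPULATION, RiskCurves, StrataHr,
                        pool_group_estimates,
                        stratified_cumulative_incidence)
from .cox import (DEFAULT_GROUP_SPEC, AgeQuartiles, HrEstimate, PgsGroupSpec,
                  assign_pgs_groups, compute_age_quartiles,
                  fit_cox_age_intervals, fit_cox_by_sex, fit_cox_full,
                  fit_cox_pgs_groups, fit_sex_interaction,
                  restrict_to_interval, standardize_pgs)
from .meta import (ALPHA_MAIN, AgeTrend, MetaEstimate, ModelChoice,
                   ModelEvidence, age_trend_wls, cochran_q,
                   compare_sex_slopes, filter_complete_studies, meta_fixed,
                   select_model)
from .screening import ScreeningResult, screening_report
from .simulate import SimConfig, derive_population_rates, simulate_multistudy
from .uncertainty import BootstrapConfig, bootstrap_curves

__all__ = ["PgsIncidenceModel", "PgsIncidenceResults"]

_SEXES = ("female", "male")


def _as_hr(meta: MetaEstimate, label: str) -> HrEstimate:
    return HrEstimate(stratum=label, log_hr=meta.log_hr, se=meta.se,
                      n_cases=0, n_controls=0, converged=np.isfinite(meta.se))


class PgsIncidenceModel:
    """PGS-stratified cumulative-incidence model for one disease.

    Parameters
    ----------
    cohorts : DataFrame or sequence of DataFrames
        Individual-level records (columns ``study, iid, sex, pgs, status,
        exit_age``); one frame per study or a single pooled frame with a
        ``study`` column.
    rates : DataFrame
        GBD-style population rate table (see :mod:`pgsrisk.lifetable`).
    group_spec : PgsGroupSpec
        PGS percentile grouping; default <20 / 20-40 / 40-60 (reference) /
        60-80 / 80-90 / 90-95 / >95.
    """

    def __init__(self, cohorts, rates: pd.DataFrame,
                 group_spec: PgsGroupSpec = DEFAULT_GROUP_SPEC,
                 location: str | None = None,
                 alpha_main: float = ALPHA_MAIN, alpha_slope: float = 0.05,
                 max_age: float = 80.0):
        if isinstance(cohorts, pd.DataFrame):
            cohorts = [g for _, g in cohorts.groupby("study", observed=True)]
        self.cohorts = [standardize_pgs(c) for c in cohorts]
        self.rates = rates
        self.group_spec = group_spec
        self.location = (location if location is not None
                         else str(rates["location"].iloc[0]))
        self.alpha_main = alpha_main
        self.alpha_slope = alpha_slope
        self.max_age = max_age

    @classmethod
    def from_simulation(cls, config: SimConfig, **kwargs
                        ) -> "PgsIncidenceModel":
        """Simulate cohorts and the matching rate table, then build."""
        cohorts = simulate_multistudy(config)
        rates = derive_population_rates(config)
        return cls(cohorts, rates, location=config.location,
                   max_age=config.max_age, **kwargs)

    # ------------------------------------------------------------------
    def fit(self, model: str = "auto",
            hr_age_eval: str = "midpoint") -> "PgsIncidenceResults":
        """Run associations, meta-analysis, selection and calibration.

        ``model`` forces a family (``full``/``sex``/``age``/``age_and_sex``)
        instead of the data-driven choice (``auto``).
        """
        studies = {str(c["study"].iloc[0]): c for c in self.cohorts}
        grouped = {s: assign_pgs_groups(c, self.group_spec)
                   for s, c in studies.items()}
        quartiles = compute_age_quartiles(studies.values())

        battery = selection_battery(studies, quartiles,
                                    max_age=self.max_age)
        evidence = battery.evidence
        meta_per_sd = battery.per_sd
        meta_per_sd_sex = battery.per_sd_by_sex
        meta_inter = battery.interaction
        p_inter = battery.evidence.p_interaction
        q_meta = battery.per_sd_by_quartile
        q_meta_sex = battery.per_sd_by_quartile_sex
        trends_sex = battery.age_trend_by_sex
        trend_overall = battery.age_trend

        choice = (select_model(evidence, self.alpha_main, self.alpha_slope)
                  if model == "auto"
                  else ModelChoice(model, evidence, self.alpha_main,
                                   self.alpha_slope))

        # -- group-level HRs under the chosen family -------------------
        strata = self._build_strata(choice.choice, grouped, quartiles)
        curves = {sex: stratified_cumulative_incidence(
            self.rates, strata, location=self.location, sex=sex,
            hr_age_eval=hr_age_eval) for sex in _SEXES}

        return PgsIncidenceResults(
            model=self, quartiles=quartiles, per_sd=meta_per_sd,
            per_sd_by_sex=meta_per_sd_sex, per_sd_by_quartile=q_meta,
            per_sd_by_quartile_sex=q_meta_sex, interaction=meta_inter,
            p_interaction=p_inter, age_trend=trend_overall,
            age_trend_by_sex=trends_sex, model_choice=choice,
            strata=strata, curves=curves, hr_age_eval=hr_age_eval)

    # ------------------------------------------------------------------
    def _group_fits(self, grouped: Mapping[str, pd.DataFrame],
                    sex: str | None = None,
                    interval: tuple[float, float] | None = None
                    ) -> dict[str, MetaEstimate]:
        per_study = {}
        for s, c in grouped.items():
            sub = c if sex is None else c[c["sex"] == sex]
            entry = None
            if interval is not None:
                lo, hi = interval
                sub, exit_adj, event, entry = restrict_to_interval(
                    sub, lo, hi)
                sub = sub.assign(exit_age=exit_adj,
                                 status=np.where(event, "disease",
                                                 "censored"))
                if lo <= 0:
                    entry = None
            try:
                per_study[s] = fit_cox_pgs_groups(sub, self.group_spec,
                                                  entry=entry)
            except ValueError:
                continue
        if not per_study:
            raise ValueError("no study yields PGS-group estimates for "
                             f"sex={sex}, interval={interval}")
        return pool_group_estimates(per_study)

    def _group_trends(self, grouped, quartiles: AgeQuartiles,
                      sex: str | None) -> dict[str, object]:
        """Per-PGS-group age trends fitted on that group's quartile HRs."""
        by_interval = [self._group_fits(grouped, sex=sex, interval=iv)
                       for iv in quartiles.intervals(self.max_age)]
        constant = self._group_fits(grouped, sex=sex)
        trends: dict[str, object] = {}
        for label in self.group_spec.labels:
            if label == self.group_spec.reference:
                continue
            ests = [_as_hr(bi[label], label) if label in bi else
                    HrEstimate(label, np.nan, np.nan, 0, 0, False)
                    for bi in by_interval]
            try:
                trends[label] = age_trend_wls(ests, quartiles.median_onset)
            except ValueError:
                # too few converged quartiles: fall back to a flat trend at
                # the group's pooled constant estimate
                m = constant[label]
                trends[label] = AgeTrend(
                    slope=0.0, intercept=m.log_hr,
                    cov=np.array([[0.0, 0.0], [0.0, m.se ** 2]]),
                    age_range=(quartiles.median_onset[0],
                               quartiles.median_onset[-1]))
        return trends

    def _build_strata(self, choice: str, grouped,
                      quartiles: AgeQuartiles) -> StrataHr:
        spec = self.group_spec
        if choice == "full":
            return StrataHr.from_estimates(self._group_fits(grouped), spec)
        if choice == "sex":
            per_sex = {sex: {lab: _as_hr(m, lab) for lab, m in
                             self._group_fits(grouped, sex=sex).items()}
                       for sex in _SEXES}
            return StrataHr.from_sex_estimates(per_sex, spec)
        if choice == "age":
            return StrataHr.from_age_trends(
                self._group_trends(grouped, quartiles, sex=None), spec)
        if choice == "age_and_sex":
            per_sex = {sex: self._group_trends(grouped, quartiles, sex=sex)
                       for sex in _SEXES}
            trends = {lab: {sex: per_sex[sex][lab] for sex in _SEXES}
                      for lab in spec.labels if lab != spec.reference}
            return StrataHr.from_age_trends(trends, spec)
        raise ValueError(f"unknown model family {choice!r}")


@dataclass
class SelectionBattery:
    """Pooled association estimates and the model-selection evidence."""

    per_sd: MetaEstimate
    per_sd_by_sex: dict[str, MetaEstimate]
    per_sd_by_quartile: list[HrEstimate]
    per_sd_by_quartile_sex: dict[str, list[HrEstimate]]
    interaction: MetaEstimate
    age_trend: AgeTrend
    age_trend_by_sex: dict[str, AgeTrend | None]
    evidence: ModelEvidence


def _pool_quartiles(per_study_q: Mapping[str, Sequence[HrEstimate]]
                    ) -> list[HrEstimate]:
    kept, _dropped = filter_complete_studies(per_study_q)
    if not kept:       # no study converged in all quartiles: pool what exists
        kept = per_study_q
    out = []
    for i in range(4):
        ests = [kept[s][i] for s in kept]
        usable = [e for e in ests if e.converged and e.se > 0]
        if usable:
            out.append(_as_hr(meta_fixed(usable), f"age_q{i + 1}"))
        else:
            out.append(HrEstimate(f"age_q{i + 1}", np.nan, np.nan, 0, 0,
                                  converged=False))
    return out


def selection_battery(studies: Mapping[str, pd.DataFrame],
                      quartiles: AgeQuartiles, *,
                      max_age: float = 80.0) -> SelectionBattery:
    """Per-study association battery pooled into model-selection evidence.

    Runs the full-sample, per-sex, PGS-by-sex-interaction and
    onset-age-quartile Cox fits for every study, pools each stratum by
    fixed-effects meta-analysis (dropping studies incomplete in a scheme),
    fits the per-sex age trends and assembles the p-values the selection
    rules consume.
    """
    per_sd = {s: fit_cox_full(c) for s, c in studies.items()}
    per_sd_sex = {s: fit_cox_by_sex(c) for s, c in studies.items()}
    interactions = {s: fit_sex_interaction(c) for s, c in studies.items()}
    per_sd_q = {s: fit_cox_age_intervals(c, quartiles, max_age=max_age)
                for s, c in studies.items()}
    per_sd_q_sex = {
        s: {sex: fit_cox_age_intervals(
            c[c["sex"] == sex], quartiles, covariates=["pgs"],
            max_age=max_age) for sex in _SEXES}
        for s, c in studies.items()}

    meta_per_sd = meta_fixed(list(per_sd.values()))
    meta_per_sd_sex = {
        sex: meta_fixed([per_sd_sex[s][sex] for s in studies])
        for sex in _SEXES}
    inter_est = [HrEstimate("interaction", i.log_hr, i.se, 0, 0,
                            i.converged) for i in interactions.values()]
    meta_inter = meta_fixed(inter_est)
    p_inter = float(2 * _norm_sf(abs(meta_inter.log_hr / meta_inter.se)))

    q_meta = _pool_quartiles(per_sd_q)
    q_meta_sex = {sex: _pool_quartiles(
        {s: per_sd_q_sex[s][sex] for s in studies}) for sex in _SEXES}
    p_q = _q_p(q_meta)
    p_q_sex = {sex: _q_p(q_meta_sex[sex]) for sex in _SEXES}

    trends_sex: dict[str, AgeTrend | None] = {}
    p_slope = None
    for sex in _SEXES:
        try:
            trends_sex[sex] = age_trend_wls(q_meta_sex[sex],
                                            quartiles.median_onset)
        except ValueError:
            trends_sex[sex] = None
    if trends_sex["female"] is not None and trends_sex["male"] is not None:
        _, p_slope = compare_sex_slopes(trends_sex["female"],
                                        trends_sex["male"])
    trend_overall = age_trend_wls(q_meta, quartiles.median_onset)

    evidence = ModelEvidence(
        p_interaction=p_inter, p_q_age=p_q,
        p_q_age_female=p_q_sex["female"], p_q_age_male=p_q_sex["male"],
        p_slope_diff=p_slope)
    return SelectionBattery(
        per_sd=meta_per_sd, per_sd_by_sex=meta_per_sd_sex,
        per_sd_by_quartile=q_meta, per_sd_by_quartile_sex=q_meta_sex,
        interaction=meta_inter, age_trend=trend_overall,
        age_trend_by_sex=trends_sex, evidence=evidence)


def _norm_sf(z):
    from scipy import stats
    return stats.norm.sf(z)


def _q_p(estimates: Sequence[HrEstimate]) -> float | None:
    usable = [e for e in estimates if e.converged and e.se > 0]
    if len(usable) < 2:
        return None
    _, _, p = cochran_q(usable)
    return p


@dataclass
class PgsIncidenceResults:
    """Fitted estimates, model choice, curves and screening machinery."""

    model: PgsIncidenceModel
    quartiles: AgeQuartiles
    per_sd: MetaEstimate
    per_sd_by_sex: dict[str, MetaEstimate]
    per_sd_by_quartile: list[HrEstimate]
    per_sd_by_quartile_sex: dict[str, list[HrEstimate]]
    interaction: MetaEstimate
    p_interaction: float
    age_trend: AgeTrend
    age_trend_by_sex: dict[str, AgeTrend | None]
    model_choice: ModelChoice
    strata: StrataHr
    curves: dict[str, RiskCurves]
    hr_age_eval: str
    _bands: dict[str, RiskCurves] = field(default_factory=dict)

    # -- presentation ---------------------------------------------------
    def summary(self) -> str:
        ev = self.model_choice.evidence
        lines = [
            "PGS-stratified cumulative incidence model",
            "=" * 57,
            f"Studies: {len(self.model.cohorts)}   "
            f"Location: {self.model.location}   "
            f"Model family: {self.model_choice.choice}",
            "",
            "Per-SD log HR (fixed-effects meta-analysis)",
            f"  pooled  {self.per_sd.log_hr:8.4f}  (se {self.per_sd.se:.4f},"
            f"  HR {self.per_sd.hr:.3f},  k={self.per_sd.k})",
        ]
        for sex in _SEXES:
            m = self.per_sd_by_sex[sex]
            lines.append(f"  {sex:<7}{m.log_hr:8.4f}  (se {m.se:.4f},"
                         f"  HR {m.hr:.3f})")
        lines += [
            "",
            "Stratification tests "
            f"(alpha_main={self.model_choice.alpha_main:.2e}, "
            f"alpha_slope={self.model_choice.alpha_slope:g})",
            f"  PGS x sex interaction p : {_fmt_p(ev.p_interaction)}",
            f"  Q across age quartiles  : {_fmt_p(ev.p_q_age)}",
            f"    female                : {_fmt_p(ev.p_q_age_female)}",
            f"    male                  : {_fmt_p(ev.p_q_age_male)}",
            f"  slope equality (sexes)  : {_fmt_p(ev.p_slope_diff)}",
            "",
            f"Age trend of per-SD log HR: slope {self.age_trend.slope:+.5f}"
            f"/yr (se {self.age_trend.slope_se:.5f}), onset-age range "
            f"[{self.age_trend.age_range[0]:.1f}, "
            f"{self.age_trend.age_range[1]:.1f}]",
            "",
            "Quartile log HRs (pooled)",
        ]
        for e, a in zip(self.per_sd_by_quartile, self.quartiles.median_onset):
            lines.append(f"  median onset {a:5.1f}y : "
                         f"{e.log_hr:8.4f} (se {e.se:.4f})")
        lines.append("")
        lines.append("Cumulative incidence at 80 by stratum")
        for sex in _SEXES:
            cv = self.curves[sex]
            vals = "  ".join(f"{lab}={cv.curve(lab)[-1]:.3f}"
                             for lab in cv.strata)
            lines.append(f"  {sex}: {vals}")
        return "\n".join(lines)

    def hr_frame(self) -> pd.DataFrame:
        rows = [{"stratum": "full", "log_hr": self.per_sd.log_hr,
                 "se": self.per_sd.se}]
        rows += [{"stratum": f"sex:{s}",
                  "log_hr": self.per_sd_by_sex[s].log_hr,
                  "se": self.per_sd_by_sex[s].se} for s in _SEXES]
        rows += [{"stratum": e.stratum, "log_hr": e.log_hr, "se": e.se}
                 for e in self.per_sd_by_quartile]
        return pd.DataFrame(rows)

    # -- downstream -----------------------------------------------------
    def bootstrap_bands(self, config: BootstrapConfig,
                        sex: str = "female") -> RiskCurves:
        """Percentile bands for the per-stratum curves of one sex."""
        banded = bootstrap_curves(self.model.rates, self.strata, config,
                                  location=self.model.location, sex=sex,
                                  hr_age_eval=self.hr_age_eval)
        self._bands[sex] = banded
        return banded

    def screening(self, index_age: float, sex: str = "female",
                  bootstrap: BootstrapConfig | None = None
                  ) -> ScreeningResult:
        """Threshold-crossing ages against the population risk at
        ``index_age``."""
        return screening_report(
            self.curves[sex], index_age,
            rates=self.model.rates if bootstrap else None,
            strata=self.strata if bootstrap else None,
            bootstrap=bootstrap, reference=self.model.group_spec.reference,
            hr_age_eval=self.hr_age_eval)

    def plot(self, sex: str = "female", ax=None, strata=None):
        """Cumulative-incidence curves (and bands, if computed) vs age."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        cv = self._bands.get(sex, self.curves[sex])
        labels = strata or cv.strata
        for lab in labels:
            line, = ax.plot(cv.ages, cv.curve(lab), label=lab,
                            lw=2 if lab == POPULATION else 1.2)
            if cv.bands and lab in cv.bands:
                lo, hi = cv.bands[lab]
                ax.fill_between(cv.ages, lo, hi, alpha=0.2,
                                color=line.get_color())
        ax.set_xlabel("age (years)")
        ax.set_ylabel("cumulative incidence")
        ax.set_title(f"{self.model.location}, {sex}")
        ax.legend(fontsize=8)
        return ax


def _fmt_p(p) -> str:
    return "n/a" if p is None or not np.isfinite(p) else f"{p:.3g}"
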