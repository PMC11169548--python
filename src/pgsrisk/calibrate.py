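"""Recalibration of population incidence across PGS strata.

The population incidence at each age is a mixture over PGS groups.  Given
group proportions ``n_i/n`` and hazard ratios ``HR_i`` versus the reference
group (HR 1), the reference-group incidence is

    I_0 = n * I / (n_0 + sum_i HR_i * n_i)

and the i-th group's incidence is ``I_i = I_0 * HR_i``, so that the
proportion-weighted mean of the group incidences reproduces the population
incidence exactly at every age.  Group incidences are converted to hazards
with the population point prevalence, and each group's cumulative incidence
is computed by the competing-risk life table with other-cause mortality
shared across groups.

Hazard ratios may be constant, sex-specific, or age-varying through a fitted
:class:`~pgsrisk.meta.AgeTrend` (evaluated at the 5-year bin midpoint by
default, with constant extrapolation outside the fitted onset-age range).
Meta-analyzed HRs can be substituted to transfer the model to a country
whose baseline rates come from its own GBD extract.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .cox import HrEstimate, PgsGroupSpec
from .lifetable import LifeTable, hazard_from_rates, other_cause_mortality
from .meta import AgeTrend, MetaEstimate, meta_fixed

__all__ = [
    "GroupEffect",
    "StrataHr",
    "RiskCurves",
    "predict_hr_by_age",
    "reference_incidence",
    "group_incidences",
    "stratified_cumulative_incidence",
    "transfer_with_meta_hrs",
    "pool_group_estimates",
]

POPULATION = "population"


def predict_hr_by_age(trend: AgeTrend, ages) -> np.ndarray:
    """HR at each age: exp(intercept + slope * age), clamped outside range."""
    return trend.predict_hr(ages)


@dataclass(frozen=True)
class GroupEffect:
    """One PGS group's effect: log HR vs reference, possibly per sex/age.

    ``log_hr`` may be a float, an :class:`AgeTrend`, or a dict keyed by sex
    whose values are floats or AgeTrends.  ``se`` carries the standard error
    for bootstrap perturbation (float or per-sex dict; ignored for trends,
    whose covariance lives on the AgeTrend).
    """

    label: str
    proportion: float
    log_hr: object = 0.0
    se: object = None

    def log_hr_at(self, sex: str, ages: np.ndarray,
                  shift: float | Mapping[str, float] = 0.0) -> np.ndarray:
        spec = self.log_hr
        if isinstance(spec, Mapping):
            spec = spec[sex]
        if isinstance(shift, Mapping):
            shift = shift.get(sex, 0.0)
        ages = np.asarray(ages, dtype=float)
        if isinstance(spec, AgeTrend):
            return spec.predict_log_hr(ages) + shift
        return np.full_like(ages, float(spec) + shift)

    def se_at(self, sex: str) -> float:
        if self.se is None:
            return np.nan
        return float(self.se[sex] if isinstance(self.se, Mapping) else self.se)


@dataclass(frozen=True)
class StrataHr:
    """Proportions and HRs for all PGS groups, reference HR fixed at 1."""

    groups: tuple[GroupEffect, ...]
    reference: str

    def __post_init__(self) -> None:
        labels = [g.label for g in self.groups]
        if self.reference not in labels:
            raise ValueError("reference group missing from strata")
        total = sum(g.proportion for g in self.groups)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"group proportions sum to {total}, not 1")
        ref = self.groups[labels.index(self.reference)]
        probe = ref.log_hr_at("female", np.array([0.0, 40.0, 80.0]))
        if np.any(probe != 0.0):
            raise ValueError("reference group must have HR exactly 1")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(g.label for g in self.groups)

    @property
    def proportions(self) -> np.ndarray:
        return np.asarray([g.proportion for g in self.groups])

    def hr_matrix(self, sex: str, ages) -> np.ndarray:
        """(n_groups, n_ages) HR matrix at the given evaluation ages."""
        ages = np.asarray(ages, dtype=float)
        return np.exp(np.vstack([g.log_hr_at(sex, ages)
                                 for g in self.groups]))

    @classmethod
    def from_estimates(cls, estimates: Mapping[str, HrEstimate | MetaEstimate],
                       spec: PgsGroupSpec) -> "StrataHr":
        """Constant-HR strata from per-group (meta-)estimates."""
        groups = []
        for label, prop in zip(spec.labels, spec.proportions):
            if label == spec.reference:
                groups.append(GroupEffect(label, prop, 0.0, 0.0))
                continue
            est = estimates[label]
            groups.append(GroupEffect(label, prop, float(est.log_hr),
                                      float(est.se)))
        return cls(groups=tuple(groups), reference=spec.reference)

    @classmethod
    def from_sex_estimates(cls, per_sex: Mapping[str, Mapping[str, HrEstimate]],
                           spec: PgsGroupSpec) -> "StrataHr":
        groups = []
        for label, prop in zip(spec.labels, spec.proportions):
            if label == spec.reference:
                groups.append(GroupEffect(label, prop, 0.0, 0.0))
                continue
            groups.append(GroupEffect(
                label, prop,
                {s: float(per_sex[s][label].log_hr) for s in per_sex},
                {s: float(per_sex[s][label].se) for s in per_sex}))
        return cls(groups=tuple(groups), reference=spec.reference)

    @classmethod
    def from_age_trends(cls, trends: Mapping[str, object],
                        spec: PgsGroupSpec) -> "StrataHr":
        """Age-varying strata; ``trends[label]`` is an AgeTrend or a per-sex
        dict of AgeTrends."""
        groups = []
        for label, prop in zip(spec.labels, spec.proportions):
            if label == spec.reference:
                groups.append(GroupEffect(label, prop, 0.0, 0.0))
                continue
            groups.append(GroupEffect(label, prop, trends[label], None))
        return cls(groups=tuple(groups), reference=spec.reference)


def reference_incidence(incidence, proportions, hrs):
    """Eq.-5 style reference-group incidence.

    ``I_0 = I / sum_i (n_i/n) * HR_i`` with the reference's HR equal to 1;
    vectorized over age bins (``incidence`` shape (n_ages,), ``hrs`` shape
    (n_groups, n_ages) or (n_groups,)).
    """
    incidence = np.asarray(incidence, dtype=float)
    proportions = np.asarray(proportions, dtype=float)
    hrs = np.asarray(hrs, dtype=float)
    if hrs.ndim == 1:
        hrs = hrs[:, None]
    denom = np.sum(proportions[:, None] * hrs, axis=0)
    if np.any(denom <= 0):
        raise ZeroDivisionError("mixture denominator is not positive")
    return incidence / denom


def group_incidences(i0, hrs):
    """Eq.-6 style group incidences I_i = I_0 * HR_i (reference: I_0)."""
    i0 = np.asarray(i0, dtype=float)
    if np.any(i0 < 0):
        raise ValueError("reference incidence must be >= 0")
    return np.asarray(hrs, dtype=float) * i0


@dataclass(frozen=True)
class RiskCurves:
    """Per-stratum cumulative-incidence curves for one (location, sex).

    ``tables`` maps stratum label -> LifeTable; the population (unstratified)
    curve is under :data:`POPULATION`.  ``bands`` optionally maps labels to
    (lower, upper) arrays on the same boundary grid.
    """

    location: str
    sex: str
    tables: Mapping[str, LifeTable]
    bands: Mapping[str, tuple[np.ndarray, np.ndarray]] | None = None

    @property
    def ages(self) -> np.ndarray:
        return next(iter(self.tables.values())).boundaries

    @property
    def strata(self) -> tuple[str, ...]:
        return tuple(self.tables)

    def curve(self, stratum: str) -> np.ndarray:
        return self.tables[stratum].cum_inc

    def curve_at(self, stratum: str, ages) -> np.ndarray:
        return self.tables[stratum].cum_inc_at(ages)

    def with_bands(self, bands) -> "RiskCurves":
        return replace(self, bands=bands)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        ages = self.ages
        for label, lt in self.tables.items():
            ci = lt.cum_inc
            lo = up = np.full_like(ci, np.nan)
            if self.bands and label in self.bands:
                lo, up = self.bands[label]
            for a, c, l, u in zip(ages, ci, lo, up):
                rows.append({"location": self.location, "sex": self.sex,
                             "stratum": label, "age": a,
                             "cumulative_incidence": c,
                             "lower": l, "upper": u})
        return pd.DataFrame(rows)


def _rates_for(rates: pd.DataFrame, location: str, sex: str) -> pd.DataFrame:
    g = rates[(rates["location"] == location) & (rates["sex"] == sex)]
    if g.empty:
        raise KeyError(f"no rates for ({location!r}, {sex!r})")
    return g.sort_values("age_lower").reset_index(drop=True)


def stratified_cumulative_incidence(rates: pd.DataFrame, strata: StrataHr,
                                    *, location: str, sex: str,
                                    hr_age_eval: str = "midpoint",
                                    width: float = 5.0) -> RiskCurves:
    """Per-PGS-group cumulative-incidence curves for one (location, sex).

    Per age bin the population incidence is split across groups (reference
    incidence then per-group HRs), converted to hazards using the population
    point prevalence, and run through the competing-risk life table with
    other-cause mortality shared across groups.  Age-varying HRs are
    evaluated at the bin midpoint (``hr_age_eval="midpoint"``) or lower
    bound (``"lower"``).
    """
    g = _rates_for(rates, location, sex)
    age_lower = g["age_lower"].to_numpy(dtype=float)
    if hr_age_eval == "midpoint":
        eval_ages = age_lower + width / 2.0
    elif hr_age_eval == "lower":
        eval_ages = age_lower
    else:
        raise ValueError("hr_age_eval must be 'midpoint' or 'lower'")

    incidence = g["incidence"].to_numpy(dtype=float)
    prevalence = g["prevalence"].to_numpy(dtype=float)
    mort = other_cause_mortality(g["all_cause_mortality"].to_numpy(float),
                                 g["cause_mortality"].to_numpy(float))
    hrs = strata.hr_matrix(sex, eval_ages)                # (groups, bins)
    i0 = reference_incidence(incidence, strata.proportions, hrs)
    inc_groups = group_incidences(i0, hrs)

    tables = {POPULATION: LifeTable(
        age_lower=age_lower,
        hazard=hazard_from_rates(incidence, prevalence),
        mortality=mort, width=width)}
    for label, inc_i in zip(strata.labels, inc_groups):
        tables[label] = LifeTable(
            age_lower=age_lower,
            hazard=hazard_from_rates(inc_i, prevalence),
            mortality=mort, width=width)
    return RiskCurves(location=location, sex=sex, tables=tables)


def pool_group_estimates(per_study: Mapping[str, Mapping[str, HrEstimate]]
                         ) -> dict[str, MetaEstimate]:
    """Fixed-effects pooling of per-study, per-PGS-group estimates."""
    labels: list[str] = []
    for ests in per_study.values():
        for label in ests:
            if label not in labels:
                labels.append(label)
    pooled = {}
    for label in labels:
        ests = [per_study[s][label] for s in per_study
                if label in per_study[s]]
        if all(e.se == 0 and e.log_hr == 0 for e in ests):
            # reference group: the comparator, not an estimate
            pooled[label] = MetaEstimate(log_hr=0.0, se=0.0, q=0.0, df=0,
                                         p_q=1.0, k=len(ests))
        else:
            pooled[label] = meta_fixed(ests)
    return pooled


def transfer_with_meta_hrs(country_rates: pd.DataFrame,
                           meta_strata: StrataHr, *, location: str,
                           sex: str, **kwargs) -> RiskCurves:
    """Country-transfer: meta-analyzed HRs on a country's own baseline."""
    return stratified_cumulative_incidence(country_rates, meta_strata,
                                           location=location, sex=sex,
                                           **kwargs)
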