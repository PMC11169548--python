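"""Parametric bootstrap bands for risk curves and derived scalars.

Every replicate redraws the estimated parameters from their sampling
distributions — baseline GBD rates log-normally (SD from the 95% UI
half-width / 1.96 on the log scale; prevalence on the logit scale), log
hazard ratios normally with their standard errors (independently across
strata), and age-trend coefficients from the joint normal with the WLS
covariance — then recomputes the cumulative-incidence curves.  Pointwise
percentile bands (2.5/97.5 by default) follow the same recipe as the
original analysis, which recomputed the curves 1000 times.

Two modes exist for age-varying HRs: sampling the fitted (slope, intercept)
from their covariance (default) or re-perturbing the four quartile log HRs
and refitting the weighted regression inside each replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .calibrate import RiskCurves, StrataHr, stratified_cumulative_incidence
from .meta import AgeTrend, age_trend_wls

__all__ = [
    "BootstrapConfig",
    "bootstrap_curves",
    "bootstrap_scalar",
    "ci_overlap",
]

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap settings: replicate count, seed, percentiles, blocks.

    ``perturb`` selects which parameter blocks are redrawn: ``"rates"``
    (baseline incidence/prevalence/mortality), ``"log_hr"`` (group HRs) and
    ``"age_trend"`` (WLS trend coefficients).  ``trend_mode`` is ``"trend"``
    (sample fitted coefficients) or ``"refit"`` (perturb quartile HRs and
    refit; requires quartile data).
    """

    replicates: int = 1000
    seed: int = 0
    percentiles: tuple[float, float] = (2.5, 97.5)
    perturb: tuple[str, ...] = ("rates", "log_hr", "age_trend")
    trend_mode: str = "trend"

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("need at least 2 bootstrap replicates")
        lo, hi = self.percentiles
        if not 0.0 < lo < hi < 100.0:
            raise ValueError("percentiles must satisfy 0 < lower < upper < 100")
        unknown = set(self.perturb) - {"rates", "log_hr", "age_trend"}
        if unknown:
            raise ValueError(f"unknown perturbation blocks: {sorted(unknown)}")
        if self.trend_mode not in ("trend", "refit"):
            raise ValueError("trend_mode must be 'trend' or 'refit'")


# ---------------------------------------------------------------------------
# parameter perturbation
# ---------------------------------------------------------------------------

def _log_sd_from_bounds(point, lower, upper):
    point = np.asarray(point, dtype=float)
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    sd = np.zeros_like(point)
    ok = (point > 0) & (lower > 0) & (upper > 0)
    sd[ok] = (np.log(upper[ok]) - np.log(lower[ok])) / (2 * _Z95)
    return sd


def _perturb_rates(rates: pd.DataFrame, rng: np.random.Generator
                   ) -> pd.DataFrame:
    need = [c + s for c in ("incidence", "prevalence", "all_cause_mortality",
                            "cause_mortality")
            for s in ("_lower", "_upper")]
    missing = [c for c in need if c not in rates.columns]
    if missing:
        raise ValueError(
            "rate perturbation requested but uncertainty bounds are "
            f"missing: {missing}")
    out = rates.copy()
    n = len(out)
    for col in ("incidence", "all_cause_mortality", "cause_mortality"):
        sd = _log_sd_from_bounds(out[col], out[col + "_lower"],
                                 out[col + "_upper"])
        out[col] = out[col].to_numpy(float) * np.exp(
            rng.standard_normal(n) * sd)
    p = out["prevalence"].to_numpy(float)
    sd = _log_sd_from_bounds(p / np.maximum(1 - p, 1e-300),
                             out["prevalence_lower"] /
                             np.maximum(1 - out["prevalence_lower"], 1e-300),
                             out["prevalence_upper"] /
                             np.maximum(1 - out["prevalence_upper"], 1e-300))
    with np.errstate(divide="ignore"):
        logit = np.log(p) - np.log1p(-p)
    drawn = logit + rng.standard_normal(n) * sd
    newp = 1.0 / (1.0 + np.exp(-drawn))
    out["prevalence"] = np.where(p > 0, newp, 0.0)
    # other-cause mortality must remain non-negative
    out["all_cause_mortality"] = np.maximum(
        out["all_cause_mortality"], out["cause_mortality"])
    return out


def _perturb_effect_spec(spec, se, rng: np.random.Generator,
                         do_loghr: bool, do_trend: bool, mode: str,
                         refit=None):
    if isinstance(spec, Mapping):
        return {s: _perturb_effect_spec(
            spec[s], se[s] if isinstance(se, Mapping) else se, rng,
            do_loghr, do_trend, mode,
            refit[s] if isinstance(refit, Mapping) and s in refit else None)
            for s in spec}
    if isinstance(spec, AgeTrend):
        if not do_trend:
            return spec
        if mode == "refit" and refit is not None:
            ests, ages = refit
            jittered = [replace(e, log_hr=e.log_hr
                                + rng.standard_normal() * e.se)
                        for e in ests]
            return age_trend_wls(jittered, ages)
        draw = rng.multivariate_normal([spec.slope, spec.intercept],
                                       spec.cov)
        return replace(spec, slope=float(draw[0]), intercept=float(draw[1]))
    if not do_loghr:
        return spec
    se_val = float(se) if se is not None else np.nan
    if not np.isfinite(se_val):
        raise ValueError("log-HR perturbation requested but SE is missing")
    if se_val == 0.0:
        return spec
    return float(spec) + rng.standard_normal() * se_val


def _perturb_strata(strata: StrataHr, rng: np.random.Generator,
                    config: BootstrapConfig,
                    refit_data: Mapping | None) -> StrataHr:
    do_loghr = "log_hr" in config.perturb
    do_trend = "age_trend" in config.perturb
    if not (do_loghr or do_trend):
        return strata
    groups = []
    for g in strata.groups:
        if g.label == strata.reference:
            groups.append(g)
            continue
        refit = refit_data.get(g.label) if refit_data else None
        new = _perturb_effect_spec(g.log_hr, g.se, rng, do_loghr, do_trend,
                                   config.trend_mode, refit)
        groups.append(replace(g, log_hr=new))
    return replace(strata, groups=tuple(groups))


def _replicate_inputs(rates, strata, config, rng, refit_data):
    r = _perturb_rates(rates, rng) if "rates" in config.perturb else rates
    s = _perturb_strata(strata, rng, config, refit_data)
    return r, s


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def bootstrap_curves(rates: pd.DataFrame, strata: StrataHr,
                     config: BootstrapConfig, *, location: str, sex: str,
                     refit_data: Mapping | None = None,
                     **curve_kwargs) -> RiskCurves:
    """Pointwise percentile bands for all strata (and the population curve).

    Deterministic for a fixed ``config.seed``.  Returns the point-estimate
    curves with ``bands`` attached per stratum.
    """
    point = stratified_cumulative_incidence(rates, strata,
                                            location=location, sex=sex,
                                            **curve_kwargs)
    rng = np.random.default_rng(config.seed)
    stacks = {lab: [] for lab in point.strata}
    for _ in range(config.replicates):
        r, s = _replicate_inputs(rates, strata, config, rng, refit_data)
        rep = stratified_cumulative_incidence(r, s, location=location,
                                              sex=sex, **curve_kwargs)
        for lab in stacks:
            stacks[lab].append(rep.curve(lab))
    lo_p, hi_p = config.percentiles
    bands = {}
    for lab, arrs in stacks.items():
        mat = np.vstack(arrs)
        bands[lab] = (np.percentile(mat, lo_p, axis=0),
                      np.percentile(mat, hi_p, axis=0))
    return point.with_bands(bands)


@dataclass(frozen=True)
class ScalarInterval:
    point: float
    lower: float
    upper: float
    n_undefined: int
    n_replicates: int
    reliable: bool


def bootstrap_scalar(fn: Callable[[RiskCurves], float], rates: pd.DataFrame,
                     strata: StrataHr, config: BootstrapConfig, *,
                     location: str, sex: str,
                     refit_data: Mapping | None = None,
                     **curve_kwargs) -> ScalarInterval:
    """Percentile interval for a scalar functional of the risk curves.

    ``fn`` maps a :class:`RiskCurves` to a float and may return NaN for
    "not reached" replicates; these are counted, excluded from the
    percentiles, and the interval is flagged unreliable if they exceed half
    the replicates.
    """
    point_curves = stratified_cumulative_incidence(
        rates, strata, location=location, sex=sex, **curve_kwargs)
    point = float(fn(point_curves))
    rng = np.random.default_rng(config.seed)
    vals = np.empty(config.replicates)
    for i in range(config.replicates):
        r, s = _replicate_inputs(rates, strata, config, rng, refit_data)
        rep = stratified_cumulative_incidence(r, s, location=location,
                                              sex=sex, **curve_kwargs)
        vals[i] = fn(rep)
    defined = vals[np.isfinite(vals)]
    n_undef = int(config.replicates - len(defined))
    reliable = n_undef <= config.replicates // 2
    if not reliable:
        warnings.warn("more than half of the bootstrap replicates did not "
                      "define the statistic; interval unreliable")
    if len(defined) == 0:
        lo = hi = np.nan
    else:
        lo, hi = np.percentile(defined, config.percentiles)
    return ScalarInterval(point=point, lower=float(lo), upper=float(hi),
                          n_undefined=n_undef,
                          n_replicates=config.replicates, reliable=reliable)


def ci_overlap(curves_a: RiskCurves, curves_b: RiskCurves,
               strata: Sequence[str] | None = None) -> dict:
    """Fraction of grid points where b's point estimate lies in a's band.

    Used to judge whether transferred (meta-HR) curves are consistent with
    the original country-specific estimates.
    """
    if curves_a.bands is None:
        raise ValueError("curves_a has no confidence bands")
    if not np.array_equal(curves_a.ages, curves_b.ages):
        raise ValueError("age grids differ between the two curve sets")
    labels = list(strata) if strata is not None else [
        s for s in curves_a.strata if s in curves_b.strata]
    per_stratum = {}
    total = hits = 0
    for lab in labels:
        lo, hi = curves_a.bands[lab]
        b = curves_b.curve(lab)
        inside = (b >= lo) & (b <= hi)
        per_stratum[lab] = float(np.mean(inside))
        hits += int(np.sum(inside))
        total += len(inside)
    return {"per_stratum": per_stratum,
            "fraction_within": hits / total if total else np.nan,
            "n_points": total}
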