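"""Fixed-effects meta-analysis, heterogeneity tests and model selection.

Per-study stratum log hazard ratios are pooled with inverse-variance
weights; heterogeneity across studies or across onset-age quartiles is
tested with Cochran's Q (chi-square, k-1 df).  Age trends in the per-SD log
HR are summarized by weighted linear regression of the quartile estimates on
the median onset age within each quartile, and the final model family per
disease (full / sex / age / age-and-sex) is chosen by deterministic decision
rules on the interaction, heterogeneity and slope-equality tests at a
Bonferroni-corrected threshold (0.05/18 by default, for 18 diseases).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .cox import HrEstimate

__all__ = [
    "ALPHA_MAIN",
    "MetaEstimate",
    "AgeTrend",
    "ModelEvidence",
    "ModelChoice",
    "meta_fixed",
    "cochran_q",
    "age_trend_wls",
    "compare_sex_slopes",
    "select_model",
    "filter_complete_studies",
]

#: Bonferroni-corrected significance threshold: 0.05 over 18 diseases.
ALPHA_MAIN = 0.05 / 18


@dataclass(frozen=True)
class MetaEstimate:
    """Inverse-variance pooled log HR with Cochran's Q heterogeneity."""

    log_hr: float
    se: float
    q: float
    df: int
    p_q: float
    k: int

    @property
    def hr(self) -> float:
        return float(np.exp(self.log_hr))


@dataclass(frozen=True)
class AgeTrend:
    """Linear trend of the log HR with age, from weighted least squares.

    ``predict`` clamps ages outside ``age_range`` to the nearest endpoint
    (constant extrapolation to the HR closest in age).
    """

    slope: float
    intercept: float
    cov: np.ndarray            # 2x2 covariance of (slope, intercept)
    age_range: tuple[float, float]

    def predict_log_hr(self, ages) -> np.ndarray:
        a = np.clip(np.asarray(ages, dtype=float), *self.age_range)
        return self.intercept + self.slope * a

    def predict_hr(self, ages) -> np.ndarray:
        return np.exp(self.predict_log_hr(ages))

    @property
    def slope_se(self) -> float:
        return float(np.sqrt(self.cov[0, 0]))


def _usable(estimates: Iterable[HrEstimate]) -> list[HrEstimate]:
    return [e for e in estimates
            if e.converged and np.isfinite(e.log_hr) and e.se > 0]


def meta_fixed(estimates: Sequence[HrEstimate]) -> MetaEstimate:
    """Fixed-effects (inverse-variance) pooling of log hazard ratios.

    Non-converged estimates are excluded; at least one usable estimate is
    required.  ``se = (sum of weights)^(-1/2)`` with weights ``1/se_i^2``.
    """
    use = _usable(estimates)
    if not use:
        raise ValueError("no converged estimates to meta-analyze")
    b = np.array([e.log_hr for e in use])
    w = np.array([1.0 / e.se**2 for e in use])
    pooled = float(np.sum(w * b) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    if len(use) >= 2:
        q = float(np.sum(w * (b - pooled) ** 2))
        df = len(use) - 1
        p = float(stats.chi2.sf(q, df))
    else:
        q, df, p = 0.0, 0, 1.0
    return MetaEstimate(log_hr=pooled, se=se, q=q, df=df, p_q=p, k=len(use))


def cochran_q(estimates: Sequence[HrEstimate]) -> tuple[float, int, float]:
    """Cochran's Q across estimates: Q, df = k-1, chi-square p-value."""
    use = _usable(estimates)
    if len(use) < 2:
        raise ValueError("Cochran's Q requires at least 2 estimates")
    m = meta_fixed(use)
    return m.q, m.df, m.p_q


def filter_complete_studies(per_study: dict[str, Sequence[HrEstimate]],
                            ) -> tuple[dict[str, Sequence[HrEstimate]], list[str]]:
    """Drop studies lacking a converged estimate in any stratum.

    Mirrors the inclusion rule that a study enters a stratification scheme's
    meta-analysis only if a log HR could be estimated in every stratum.
    Returns the retained mapping and the names of dropped studies.
    """
    kept, dropped = {}, []
    for study, ests in per_study.items():
        if all(e.converged and np.isfinite(e.log_hr) and e.se > 0
               for e in ests):
            kept[study] = ests
        else:
            dropped.append(study)
    return kept, dropped


def age_trend_wls(estimates: Sequence[HrEstimate],
                  ages: Sequence[float]) -> AgeTrend:
    """Weighted linear regression of quartile log HRs on median onset age.

    Weights are inverse variances (1/se^2); the coefficient covariance is
    the fixed-scale (X'WX)^{-1}, appropriate when the weights are known
    sampling variances.  Requires >= 2 points with distinct ages; with
    exactly two points the line interpolates them and the covariance is the
    exact error propagation of the two estimates.
    """
    pairs = [(e, a) for e, a in zip(estimates, ages)
             if e.converged and np.isfinite(e.log_hr) and e.se > 0]
    if len(pairs) < 2:
        raise ValueError("age trend requires at least 2 converged estimates")
    y = np.array([e.log_hr for e, _ in pairs])
    a = np.array([age for _, age in pairs], dtype=float)
    if len(np.unique(a)) < 2:
        raise ValueError("duplicate onset ages: age trend not identifiable")
    w = np.array([1.0 / e.se**2 for e, _ in pairs])
    X = np.column_stack([a, np.ones_like(a)])       # (slope, intercept)
    xtwx = X.T @ (w[:, None] * X)
    cov = np.linalg.inv(xtwx)
    beta = cov @ (X.T @ (w * y))
    return AgeTrend(slope=float(beta[0]), intercept=float(beta[1]),
                    cov=cov, age_range=(float(a.min()), float(a.max())))


def compare_sex_slopes(trend_f: AgeTrend, trend_m: AgeTrend
                       ) -> tuple[float, float]:
    """Two-sided z-test of slope equality between sexes.

    Variances are summed (the sex strata are disjoint samples, hence
    independent).  Returns (z, p).
    """
    var = trend_f.cov[0, 0] + trend_m.cov[0, 0]
    if not np.isfinite(var) or var <= 0:
        raise ValueError("slope variances unavailable for comparison")
    z = (trend_f.slope - trend_m.slope) / np.sqrt(var)
    return float(z), float(2 * stats.norm.sf(abs(z)))


@dataclass(frozen=True)
class ModelEvidence:
    """The test battery feeding the model-selection rules.

    Missing tests (None) are treated as non-significant and noted in the
    choice record.
    """

    p_interaction: float | None = None     # PGS x sex Wald p
    p_q_age: float | None = None           # Cochran's Q across age quartiles
    p_q_age_female: float | None = None
    p_q_age_male: float | None = None
    p_slope_diff: float | None = None      # slope-equality z-test p


@dataclass(frozen=True)
class ModelChoice:
    choice: str                            # full / sex / age / age_and_sex
    evidence: ModelEvidence
    alpha_main: float
    alpha_slope: float
    missing: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        ev = self.evidence
        return {
            "choice": self.choice,
            "p_interaction": ev.p_interaction,
            "p_q_age": ev.p_q_age,
            "p_q_age_female": ev.p_q_age_female,
            "p_q_age_male": ev.p_q_age_male,
            "p_slope_diff": ev.p_slope_diff,
            "alpha_main": self.alpha_main,
            "alpha_slope": self.alpha_slope,
            "missing_tests": list(self.missing),
        }


def select_model(evidence: ModelEvidence,
                 alpha_main: float = ALPHA_MAIN,
                 alpha_slope: float = 0.05) -> ModelChoice:
    """Deterministic model-family choice from the stratification tests.

    Sex-specific effects: interaction p < alpha_main.  Age-specific effects:
    quartile Q p < alpha_main.  Age-and-sex: both of the above; or Q
    significant in exactly one sex while not overall; or the age slopes
    differ between sexes at alpha_slope.  Otherwise the full (unstratified)
    model is kept.
    """
    missing = tuple(name for name in
                    ("p_interaction", "p_q_age", "p_q_age_female",
                     "p_q_age_male", "p_slope_diff")
                    if getattr(evidence, name) is None)

    def sig(p, alpha):
        return p is not None and np.isfinite(p) and p < alpha

    sex_sig = sig(evidence.p_interaction, alpha_main)
    age_sig = sig(evidence.p_q_age, alpha_main)
    single_sex_age = (not age_sig) and (
        sig(evidence.p_q_age_female, alpha_main)
        ^ sig(evidence.p_q_age_male, alpha_main))
    slope_sig = sig(evidence.p_slope_diff, alpha_slope)

    if (sex_sig and age_sig) or single_sex_age or slope_sig:
        choice = "age_and_sex"
    elif sex_sig:
        choice = "sex"
    elif age_sig:
        choice = "age"
    else:
        choice = "full"
    return ModelChoice(choice=choice, evidence=evidence,
                       alpha_main=alpha_main, alpha_slope=alpha_slope,
                       missing=missing)
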