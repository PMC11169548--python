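"""GBD-calibrated competing-risk life table on 5-year age groups.

From population incidence rates, point prevalence and mortality per
(location, sex, 5-year age group), the life table computes

* the disease hazard per person-year among the disease-free,
  ``hazard = incidence / (1 - prevalence)``;
* other-cause mortality, ``all-cause minus cause-specific``;
* survival free of both disease and death at each 5-year boundary,
  ``survival_k = exp(-5 * sum over bins below k of (mortality + hazard))``,
  with survival 1 at age 0 (hazards are per year; each bin spans 5 years);
* the within-bin disease probability ``risk_k = 1 - exp(-5 * hazard)``;
* cumulative incidence as the running sum of ``survival_k * risk_k``.

An annual sub-grid evaluation is provided for screening-age resolution: the
hazard is constant within its 5-year bin, so within a bin the curve follows
the exact constant-hazard closed form and reproduces the 5-year values at
bin boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RATE_COLUMNS",
    "read_rate_table",
    "validate_rate_table",
    "hazard_from_rates",
    "other_cause_mortality",
    "survival_curve",
    "interval_risk",
    "cumulative_incidence",
    "LifeTable",
]

RATE_COLUMNS = ("location", "sex", "age_lower", "incidence", "prevalence",
                "cause_mortality", "all_cause_mortality")
_BIN_WIDTH = 5.0
_MAX_AGE = 80.0


def validate_rate_table(df: pd.DataFrame, *, max_age: float = _MAX_AGE
                        ) -> list[str]:
    """Check schema and invariants; return a list of violation messages."""
    problems = []
    missing = set(RATE_COLUMNS) - set(df.columns)
    if missing:
        return [f"missing columns: {sorted(missing)}"]
    for (loc, sex), g in df.groupby(["location", "sex"], observed=True):
        lows = np.sort(g["age_lower"].to_numpy(dtype=float))
        expect = np.arange(0.0, max_age, _BIN_WIDTH)
        if len(lows) != len(set(lows)):
            problems.append(f"({loc}, {sex}): duplicate age bins")
        gaps = sorted(set(expect) - set(lows))
        extra = sorted(set(lows) - set(expect))
        if gaps:
            problems.append(f"({loc}, {sex}): missing age bins {gaps}")
        if extra:
            problems.append(f"({loc}, {sex}): unexpected age bins {extra}")
        for _, row in g.iterrows():
            tag = f"({loc}, {sex}, age {row['age_lower']:g})"
            if not 0.0 <= row["prevalence"] < 1.0:
                problems.append(f"{tag}: prevalence {row['prevalence']} "
                                "outside [0, 1)")
            for col in ("incidence", "cause_mortality",
                        "all_cause_mortality"):
                if row[col] < 0 or not np.isfinite(row[col]):
                    problems.append(f"{tag}: {col} = {row[col]} invalid")
            if row["cause_mortality"] > row["all_cause_mortality"] + 1e-12:
                problems.append(f"{tag}: cause-specific mortality exceeds "
                                "all-cause")
    return problems


def read_rate_table(path_or_buf, *, max_age: float = _MAX_AGE
                    ) -> pd.DataFrame:
    """Read and validate a GBD-style rate table CSV."""
    df = pd.read_csv(path_or_buf)
    problems = validate_rate_table(df, max_age=max_age)
    if problems:
        raise ValueError("invalid rate table:\n  " + "\n  ".join(problems))
    return df.sort_values(["location", "sex", "age_lower"]).reset_index(drop=True)


def hazard_from_rates(incidence, prevalence):
    """Disease hazard among the disease-free: incidence / (1 - prevalence)."""
    incidence = np.asarray(incidence, dtype=float)
    prevalence = np.asarray(prevalence, dtype=float)
    if np.any(prevalence >= 1.0) or np.any(prevalence < 0.0):
        raise ValueError("prevalence must lie in [0, 1)")
    if np.any(incidence < 0.0):
        raise ValueError("incidence must be >= 0")
    return incidence / (1.0 - prevalence)


def other_cause_mortality(all_cause, cause_specific, *, tol: float = 1e-12):
    """All-cause minus cause-specific mortality, clamped at 0 within tol."""
    all_cause = np.asarray(all_cause, dtype=float)
    cause_specific = np.asarray(cause_specific, dtype=float)
    if np.any(cause_specific < 0.0):
        raise ValueError("cause-specific mortality must be >= 0")
    diff = all_cause - cause_specific
    if np.any(diff < -tol):
        raise ValueError("cause-specific mortality exceeds all-cause")
    return np.maximum(diff, 0.0)


def survival_curve(hazard, mortality, *, width: float = _BIN_WIDTH
                   ) -> np.ndarray:
    """Survival at bin boundaries {0, w, 2w, ...}: length nbins + 1.

    ``survival_k = exp(-w * sum_{m < k} (mortality_m + hazard_m))`` with
    survival 1 at age 0.
    """
    hazard = np.asarray(hazard, dtype=float)
    mortality = np.asarray(mortality, dtype=float)
    combined = np.concatenate([[0.0], np.cumsum(mortality + hazard)])
    return np.exp(-width * combined)


def interval_risk(hazard, *, width: float = _BIN_WIDTH) -> np.ndarray:
    """Within-bin disease probability: 1 - exp(-w * hazard)."""
    hazard = np.asarray(hazard, dtype=float)
    if np.any(hazard < 0.0):
        raise ValueError("hazard must be >= 0")
    return -np.expm1(-width * hazard)


def cumulative_incidence(survival: np.ndarray, risk: np.ndarray
                         ) -> np.ndarray:
    """Cumulative incidence at bin boundaries: running sum of S_k * risk_k.

    ``survival`` has length nbins + 1 (boundaries); ``risk`` length nbins.
    Returns length nbins + 1 with value 0 at age 0.
    """
    contrib = survival[:-1] * np.asarray(risk, dtype=float)
    return np.concatenate([[0.0], np.cumsum(contrib)])


@dataclass(frozen=True)
class LifeTable:
    """Competing-risk life table for one (location, sex) stratum."""

    age_lower: np.ndarray          # bin lower bounds, len nbins
    hazard: np.ndarray             # disease hazard per person-year
    mortality: np.ndarray          # other-cause mortality per person-year
    width: float = _BIN_WIDTH

    def __post_init__(self) -> None:
        if len(self.age_lower) != len(self.hazard) or \
                len(self.hazard) != len(self.mortality):
            raise ValueError("life-table arrays must share one length")
        if np.any(self.hazard < 0) or np.any(self.mortality < 0):
            raise ValueError("hazards and mortalities must be >= 0")

    @classmethod
    def from_rates(cls, age_lower, incidence, prevalence,
                   cause_mortality, all_cause_mortality,
                   width: float = _BIN_WIDTH) -> "LifeTable":
        hazard = hazard_from_rates(incidence, prevalence)
        mort = other_cause_mortality(all_cause_mortality, cause_mortality)
        return cls(age_lower=np.asarray(age_lower, dtype=float),
                   hazard=np.asarray(hazard, dtype=float),
                   mortality=np.asarray(mort, dtype=float), width=width)

    @classmethod
    def from_rate_table(cls, rates: pd.DataFrame, *, location: str,
                        sex: str) -> "LifeTable":
        g = rates[(rates["location"] == location) & (rates["sex"] == sex)]
        if g.empty:
            raise KeyError(f"no rates for ({location!r}, {sex!r})")
        g = g.sort_values("age_lower")
        return cls.from_rates(g["age_lower"], g["incidence"],
                              g["prevalence"], g["cause_mortality"],
                              g["all_cause_mortality"])

    # -- derived quantities --------------------------------------------
    @property
    def boundaries(self) -> np.ndarray:
        return np.concatenate([self.age_lower,
                               [self.age_lower[-1] + self.width]])

    @property
    def survival(self) -> np.ndarray:
        return survival_curve(self.hazard, self.mortality, width=self.width)

    @property
    def risk(self) -> np.ndarray:
        return interval_risk(self.hazard, width=self.width)

    @property
    def cum_inc(self) -> np.ndarray:
        return cumulative_incidence(self.survival, self.risk)

    def cum_inc_at(self, ages) -> np.ndarray:
        """Cumulative incidence at arbitrary ages on the annual sub-grid.

        Within bin [m, m+w) the hazard is constant, so
        ``CI(a) = CI(m) + survival_m * (1 - exp(-h_m * (a - m)))``; at bin
        boundaries this reproduces the 5-year computation exactly.
        """
        ages = np.asarray(ages, dtype=float)
        b = self.boundaries
        if np.any(ages < b[0]) or np.any(ages > b[-1]):
            raise ValueError(f"ages must lie within [{b[0]}, {b[-1]}]")
        idx = np.clip(np.searchsorted(b, ages, side="right") - 1,
                      0, len(self.hazard) - 1)
        ci, s = self.cum_inc, self.survival
        return (ci[idx] + s[idx]
                * -np.expm1(-self.hazard[idx] * (ages - b[idx])))

    def to_frame(self) -> pd.DataFrame:
        s, r, ci = self.survival, self.risk, self.cum_inc
        return pd.DataFrame({
            "age_lower": self.age_lower,
            "hazard": self.hazard,
            "other_mortality": self.mortality,
            "survival": s[:-1],
            "risk": r,
            "cum_inc_lower_bound": ci[:-1],
            "cum_inc_upper_bound": ci[1:],
        })
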