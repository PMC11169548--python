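"""Synthetic biobank cohorts and matching population rate tables.

The generator draws individual disease histories from a proportional-hazards
model with age as the timescale: a piecewise-constant baseline disease hazard
``h0(a)``, an independent piecewise-constant other-cause mortality ``mu(a)``,
and a standard-normal polygenic score (PGS) acting multiplicatively on the
disease hazard through a possibly sex- and age-varying log hazard ratio

    log HR(a, sex) = beta0 + beta_sex * 1[male] + beta_age * (a - age_ref) + u_s

where ``u_s`` is a study-level offset (between-study heterogeneity).  The
individual hazard is ``h0(a) * exp(log HR(a, sex) * PGS)``.  Follow-up starts
at birth and ends at disease onset, death from another cause, or
administrative censoring at ``max_age`` (default 80), whichever comes first.

Event ages are sampled by exact inversion of the cumulative hazard within
each piecewise segment (the integrand is exponential in age, so the segment
integral has a closed form); there is no time-step discretization.

``derive_population_rates`` produces the GBD-style rate table (incidence,
point prevalence, cause-specific and all-cause mortality per sex and 5-year
age group) that is analytically implied by the same generative model,
marginalized over the PGS distribution by Gauss-Hermite quadrature, so that
the downstream life-table calibration can be tested against a known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "default_config",
    "simulate_cohort",
    "simulate_multistudy",
    "derive_population_rates",
    "analytic_cumulative_incidence",
    "write_cohort",
    "read_cohort",
]

_STATUSES = ("disease", "other_death", "censored")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort / population generator.

    Parameters
    ----------
    n_individuals : int
        Cohort size (per study).
    baseline_hazard : sequence of (age, rate)
        Piecewise-constant disease hazard per person-year for a PGS=0
        individual; ``age`` is the lower bound of each segment.  Segments
        must start at 0, be increasing and cover ``[0, max_age)``.
    other_mortality : sequence of (age, rate)
        Piecewise-constant other-cause mortality per person-year.
    beta0 : float
        Log hazard ratio per standard deviation of the PGS at the reference
        age, in females.
    beta_sex : float
        Additive difference in the per-SD log HR (male minus female).
    beta_age : float
        Change in the per-SD log HR per year of age relative to ``age_ref``.
    age_ref : float
        Reference age for the age trend (years).
    study_sd : float
        Between-study SD of additive log-HR offsets.
    rate_rel_se : float
        Relative standard error attached to derived population rates when
        constructing 95% uncertainty bounds (log scale).
    """

    n_individuals: int = 200_000
    n_studies: int = 1
    seed: int = 0
    sex_fraction_female: float = 0.5
    baseline_hazard: Sequence[tuple[float, float]] = field(
        default_factory=lambda: DEFAULT_BASELINE_HAZARD
    )
    other_mortality: Sequence[tuple[float, float]] = field(
        default_factory=lambda: DEFAULT_OTHER_MORTALITY
    )
    beta0: float = 0.3
    beta_sex: float = 0.0
    beta_age: float = 0.0
    age_ref: float = 40.0
    study_sd: float = 0.0
    max_age: float = 80.0
    rate_rel_se: float = 0.05
    location: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")
        if not 0.0 < self.sex_fraction_female < 1.0:
            raise ValueError("sex_fraction_female must lie strictly in (0, 1)")
        if self.study_sd < 0:
            raise ValueError("study_sd must be >= 0")
        if self.max_age <= 0:
            raise ValueError("max_age must be positive")
        for name in ("baseline_hazard", "other_mortality"):
            segs = list(getattr(self, name))
            if not segs:
                raise ValueError(f"{name} has empty age coverage")
            ages = np.asarray([a for a, _ in segs], dtype=float)
            rates = np.asarray([r for _, r in segs], dtype=float)
            if ages[0] != 0.0:
                raise ValueError(f"{name} must start at age 0")
            if np.any(np.diff(ages) <= 0):
                raise ValueError(f"{name} age bins must be strictly increasing")
            if ages[-1] >= self.max_age:
                raise ValueError(f"{name} segments must lie below max_age")
            if np.any(rates < 0) or not np.all(np.isfinite(rates)):
                raise ValueError(f"{name} rates must be finite and >= 0")

    # -- piecewise representations -------------------------------------
    def hazard_edges(self) -> tuple[np.ndarray, np.ndarray]:
        """Segment edges (len k+1, ending at max_age) and rates (len k)."""
        ages = [a for a, _ in self.baseline_hazard] + [self.max_age]
        rates = [r for _, r in self.baseline_hazard]
        return np.asarray(ages, dtype=float), np.asarray(rates, dtype=float)

    def mortality_edges(self) -> tuple[np.ndarray, np.ndarray]:
        ages = [a for a, _ in self.other_mortality] + [self.max_age]
        rates = [r for _, r in self.other_mortality]
        return np.asarray(ages, dtype=float), np.asarray(rates, dtype=float)


#: Default study conditions: a common adult-onset disease with incidence
#: rising steeply with age (lifetime risk ~20-25%, T2D-like) and a Western
#: European mortality schedule, per-SD HR exp(0.3) ~ 1.35.
DEFAULT_BASELINE_HAZARD: tuple[tuple[float, float], ...] = (
    (0, 1e-5), (5, 2e-5), (10, 5e-5), (15, 1e-4),
    (20, 2e-4), (25, 4e-4), (30, 7e-4), (35, 1.2e-3),
    (40, 2e-3), (45, 3e-3), (50, 4.5e-3), (55, 6e-3),
    (60, 8e-3), (65, 1.0e-2), (70, 1.2e-2), (75, 1.3e-2),
)
DEFAULT_OTHER_MORTALITY: tuple[tuple[float, float], ...] = (
    (0, 8e-4), (5, 1e-4), (10, 1.5e-4), (15, 4e-4),
    (20, 6e-4), (25, 7e-4), (30, 8e-4), (35, 1.1e-3),
    (40, 1.6e-3), (45, 2.5e-3), (50, 4e-3), (55, 6.5e-3),
    (60, 1.0e-2), (65, 1.6e-2), (70, 2.6e-2), (75, 4.5e-2),
)


def default_config(**overrides) -> SimConfig:
    """The packaged demo study conditions (see module docstring)."""
    return replace(SimConfig(), **overrides) if overrides else SimConfig()


# ---------------------------------------------------------------------------
# closed-form segment integrals
# ---------------------------------------------------------------------------

def _segment_cumhaz(edges: np.ndarray, rates: np.ndarray,
                    A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Per-(individual, segment) integral of h_j * exp(A + B*a) da.

    ``A``, ``B`` have shape (n,); returns shape (n, k).  Handles B == 0
    exactly (constant integrand).
    """
    a1 = edges[:-1][None, :]
    a2 = edges[1:][None, :]
    A = A[:, None]
    B = B[:, None]
    with np.errstate(over="raise"):
        out = np.where(
            B == 0.0,
            np.exp(A) * (a2 - a1),
            np.exp(A) * _expdiff(B, a1, a2),
        )
    return rates[None, :] * out


def _expdiff(B, a1, a2):
    # (exp(B*a2) - exp(B*a1)) / B, stable via expm1
    Bsafe = np.where(B == 0.0, 1.0, B)
    return np.exp(Bsafe * a1) * np.expm1(Bsafe * (a2 - a1)) / Bsafe


def _invert_in_segment(rem, rate, A, B, a1):
    """Solve rate * int_{a1}^{a} exp(A + B t) dt = rem for a."""
    base = rate * np.exp(A)
    with np.errstate(divide="ignore", invalid="ignore"):
        lin = a1 + rem / base
        Bsafe = np.where(B == 0.0, 1.0, B)
        arg = 1.0 + rem * Bsafe / (base * np.exp(Bsafe * a1))
        gen = a1 + np.log(arg) / Bsafe
    return np.where(B == 0.0, lin, gen)


def _sample_piecewise_exp(u: np.ndarray, edges: np.ndarray, rates: np.ndarray,
                          A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Exact inversion sampling of event ages; inf when no event by the end.

    ``u`` are unit-exponential targets for the cumulative hazard.
    """
    seg = _segment_cumhaz(edges, rates, A, B)          # (n, k)
    cum = np.cumsum(seg, axis=1)
    total = cum[:, -1]
    # first segment where cumulative hazard exceeds the target
    idx = np.sum(cum < u[:, None], axis=1)
    hit = u <= total
    idx_c = np.minimum(idx, len(rates) - 1)
    prev = np.where(idx_c > 0, np.take_along_axis(
        cum, np.maximum(idx_c - 1, 0)[:, None], axis=1).ravel(), 0.0)
    prev = np.where(idx_c > 0, prev, 0.0)
    rem = u - prev
    ages = _invert_in_segment(rem, rates[idx_c], A, B, edges[idx_c])
    return np.where(hit, ages, np.inf)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _linpred_coeffs(config: SimConfig, male: np.ndarray, pgs: np.ndarray,
                    study_offset: float) -> tuple[np.ndarray, np.ndarray]:
    """Return (A, B) with log individual relative hazard = A + B*age."""
    loghr_at_ref = (config.beta0 + config.beta_sex * male + study_offset)
    A = (loghr_at_ref - config.beta_age * config.age_ref) * pgs
    B = config.beta_age * pgs
    return A, B


def simulate_cohort(config: SimConfig, *, study_index: int = 0,
                    study_offset: float = 0.0,
                    study_label: str | None = None) -> pd.DataFrame:
    """Simulate one biobank-style cohort.

    Returns a DataFrame with columns ``study, iid, sex, pgs, status,
    exit_age``; status is one of ``disease``, ``other_death``, ``censored``.
    Deterministic for fixed ``(config.seed, study_index)``.
    """
    rng = np.random.default_rng([int(config.seed), int(study_index)])
    n = config.n_individuals
    male = (rng.random(n) >= config.sex_fraction_female).astype(float)
    pgs = rng.standard_normal(n)
    u_dis = rng.exponential(size=n)
    u_die = rng.exponential(size=n)

    h_edges, h_rates = config.hazard_edges()
    m_edges, m_rates = config.mortality_edges()
    A, B = _linpred_coeffs(config, male, pgs, study_offset)
    t_dis = _sample_piecewise_exp(u_dis, h_edges, h_rates, A, B)
    t_die = _sample_piecewise_exp(u_die, m_edges, m_rates,
                                  np.zeros(n), np.zeros(n))

    exit_age = np.minimum.reduce([t_dis, t_die,
                                  np.full(n, config.max_age)])
    status = np.where(
        t_dis <= exit_age, "disease",
        np.where(t_die <= exit_age, "other_death", "censored"),
    )
    label = study_label or f"study_{study_index}"
    return pd.DataFrame({
        "study": label,
        "iid": np.arange(n, dtype=np.int64),
        "sex": np.where(male == 1.0, "male", "female"),
        "pgs": pgs,
        "status": pd.Categorical(status, categories=list(_STATUSES)),
        "exit_age": exit_age,
    })


def simulate_multistudy(config: SimConfig) -> list[pd.DataFrame]:
    """One cohort per study with Normal(0, study_sd) log-HR offsets.

    The offset of each cohort is recorded in ``df.attrs["study_offset"]``
    for truth tracking.  With ``n_studies=1`` and ``study_sd=0`` the single
    cohort is identical to ``simulate_cohort(config)``.
    """
    off_rng = np.random.default_rng([int(config.seed), 999_983])
    offsets = (off_rng.standard_normal(config.n_studies) * config.study_sd
               if config.study_sd > 0 else np.zeros(config.n_studies))
    cohorts = []
    for i in range(config.n_studies):
        df = simulate_cohort(config, study_index=i,
                             study_offset=float(offsets[i]))
        df.attrs["study_offset"] = float(offsets[i])
        cohorts.append(df)
    return cohorts


# ---------------------------------------------------------------------------
# analytic population rates
# ---------------------------------------------------------------------------

_GH_NODES = 61
_GL_NODES = 16


def _cumhaz_at(ages: np.ndarray, edges: np.ndarray, rates: np.ndarray,
               A: float, B: float) -> np.ndarray:
    """Cumulative disease hazard from 0 to each age for scalar (A, B)."""
    seg = _segment_cumhaz(edges, rates, np.array([A]), np.array([B]))[0]
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    idx = np.clip(np.searchsorted(edges, ages, side="right") - 1,
                  0, len(rates) - 1)
    if B == 0.0:
        seglen = ages - edges[idx]
    else:
        seglen = _expdiff(np.full_like(ages, B, dtype=float),
                          edges[idx], ages)
    return cum[idx] + rates[idx] * np.exp(A) * seglen


def _rate_at(ages, edges, rates):
    idx = np.clip(np.searchsorted(edges, ages, side="right") - 1,
                  0, len(rates) - 1)
    return rates[idx]


def derive_population_rates(config: SimConfig, *, bin_width: float = 5.0,
                            gh_nodes: int = _GH_NODES) -> pd.DataFrame:
    """Analytic GBD-style rate table implied by the generator.

    For each sex and 5-year age group: the incidence rate per person-year
    among the alive population, the point prevalence of ever-diagnosed
    individuals at the bin midpoint, the cause-specific mortality rate
    (zero: the generator's disease is non-fatal) and the all-cause mortality
    rate.  The PGS is marginalized out by Gauss-Hermite quadrature; age
    integrals within each bin use Gauss-Legendre nodes.  95% uncertainty
    bounds are attached on the log (rates) / logit (prevalence) scale with
    relative SE ``config.rate_rel_se``.
    """
    h_edges, h_rates = config.hazard_edges()
    m_edges, m_rates = config.mortality_edges()
    z, wz = np.polynomial.hermite_e.hermegauss(gh_nodes)
    wz = wz / np.sqrt(2 * np.pi)  # weights for standard normal expectation
    xg, wg = np.polynomial.legendre.leggauss(_GL_NODES)

    bins = np.arange(0.0, config.max_age, bin_width)
    rows = []
    for sex, male in (("female", 0.0), ("male", 1.0)):
        loghr_ref = config.beta0 + config.beta_sex * male
        A_z = (loghr_ref - config.beta_age * config.age_ref) * z
        B_z = config.beta_age * z
        for lo in bins:
            hi = lo + bin_width
            ages = 0.5 * (hi - lo) * xg + 0.5 * (hi + lo)
            w_age = 0.5 * (hi - lo) * wg
            # alive probability (independent of PGS and disease status)
            S_m = np.exp(-_cumhaz_at(ages, m_edges, m_rates, 0.0, 0.0))
            person_years = float(np.sum(w_age * S_m))
            # new cases per year, marginal over PGS
            new_cases = 0.0
            prev_mid = 0.0
            mid = np.array([0.5 * (lo + hi)])
            for Az, Bz, w in zip(A_z, B_z, wz):
                lam = _cumhaz_at(ages, h_edges, h_rates, Az, Bz)
                S_d = np.exp(-lam)
                haz = (_rate_at(ages, h_edges, h_rates)
                       * np.exp(Az + Bz * ages))
                new_cases += w * float(np.sum(w_age * haz * S_d * S_m))
                prev_mid += w * float(
                    1.0 - np.exp(-_cumhaz_at(mid, h_edges, h_rates,
                                             Az, Bz)[0]))
            if not (np.isfinite(new_cases) and np.isfinite(person_years)
                    and person_years > 0):
                raise ArithmeticError(
                    f"quadrature failure in bin [{lo},{hi}) for sex {sex}")
            incidence = new_cases / person_years
            # deaths per person-year alive; mortality piecewise constant
            mort = float(np.sum(w_age * _rate_at(ages, m_edges, m_rates)
                                * S_m) / person_years)
            rows.append({
                "location": config.location, "sex": sex, "age_lower": lo,
                "incidence": incidence, "prevalence": prev_mid,
                "cause_mortality": 0.0, "all_cause_mortality": mort,
            })
    df = pd.DataFrame(rows)
    return _attach_bounds(df, config.rate_rel_se)


def _attach_bounds(df: pd.DataFrame, rel_se: float) -> pd.DataFrame:
    z95 = 1.959963984540054
    f = np.exp(z95 * rel_se)
    for col in ("incidence", "cause_mortality", "all_cause_mortality"):
        df[col + "_lower"] = df[col] / f
        df[col + "_upper"] = df[col] * f
    p = df["prevalence"].to_numpy()
    with np.errstate(divide="ignore"):
        odds = p / (1.0 - p)
    df["prevalence_lower"] = (odds / f) / (1.0 + odds / f)
    df["prevalence_upper"] = (odds * f) / (1.0 + odds * f)
    df.loc[p == 0.0, ["prevalence_lower", "prevalence_upper"]] = 0.0
    return df


def analytic_cumulative_incidence(config: SimConfig, ages: np.ndarray,
                                  *, pgs: float = 0.0, sex: str = "female",
                                  gh_nodes: int = _GH_NODES,
                                  marginal: bool = False,
                                  percentile_range: tuple[float, float]
                                  | None = None) -> np.ndarray:
    """Exact P(disease by age a) under the generator, with competing death.

    With ``marginal=True`` the PGS is integrated out (population curve for
    the given sex); ``percentile_range=(lo, hi)`` in (0, 100) instead
    averages over the corresponding slice of the PGS distribution (the
    ground truth for a percentile group's curve).  Otherwise the curve is
    for a fixed PGS value.  Computed by fine trapezoidal integration of
    f_d(a) * S_m(a).
    """
    h_edges, h_rates = config.hazard_edges()
    m_edges, m_rates = config.mortality_edges()
    male = 1.0 if sex == "male" else 0.0
    grid = np.linspace(0.0, float(np.max(ages)), 4001)
    S_m = np.exp(-_cumhaz_at(grid, m_edges, m_rates, 0.0, 0.0))

    def curve_for(zval: float) -> np.ndarray:
        A = ((config.beta0 + config.beta_sex * male
              - config.beta_age * config.age_ref) * zval)
        B = config.beta_age * zval
        lam = _cumhaz_at(grid, h_edges, h_rates, A, B)
        dens = (_rate_at(grid, h_edges, h_rates) * np.exp(A + B * grid)
                * np.exp(-lam) * S_m)
        ci = np.concatenate([[0.0], np.cumsum(
            0.5 * (dens[1:] + dens[:-1]) * np.diff(grid))])
        return np.interp(ages, grid, ci)

    if percentile_range is not None:
        from scipy import stats as _stats
        lo, hi = percentile_range
        zlo = _stats.norm.ppf(lo / 100.0) if lo > 0 else -8.0
        zhi = _stats.norm.ppf(hi / 100.0) if hi < 100 else 8.0
        xg, wg = np.polynomial.legendre.leggauss(80)
        zs = 0.5 * (zhi - zlo) * xg + 0.5 * (zhi + zlo)
        ws = 0.5 * (zhi - zlo) * wg * _stats.norm.pdf(zs)
        ws = ws / ws.sum()
        out = np.zeros_like(np.asarray(ages, dtype=float))
        for zi, wi in zip(zs, ws):
            out = out + wi * curve_for(zi)
        return out
    if not marginal:
        return curve_for(pgs)
    z, wz = np.polynomial.hermite_e.hermegauss(gh_nodes)
    wz = wz / np.sqrt(2 * np.pi)
    out = np.zeros_like(np.asarray(ages, dtype=float))
    for zi, wi in zip(z, wz):
        out = out + wi * curve_for(zi)
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path, max_age: float = 80.0) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"study": str, "sex": str, "status": str})
    missing = {"study", "iid", "sex", "pgs", "status", "exit_age"} - set(df)
    if missing:
        raise ValueError(f"cohort file missing columns: {sorted(missing)}")
    bad = set(df["status"]) - set(_STATUSES)
    if bad:
        raise ValueError(f"unknown status values: {sorted(bad)}")
    if (df["exit_age"] <= 0).any():
        raise ValueError("exit_age must be positive")
    if (df["exit_age"] > max_age).any():
        raise ValueError(f"exit_age exceeds max_age ({max_age})")
    if not np.isfinite(df["pgs"]).all():
        raise ValueError("pgs must be finite")
    return df
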