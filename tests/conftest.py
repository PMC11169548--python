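import numpy as np
import pandas as pd
import pytest

from pgsrisk.simulate import SimConfig


def flat_config(**over) -> SimConfig:
    """Constant-hazard study conditions used by several closed-form tests."""
    defaults = dict(
        n_individuals=10_000,
        baseline_hazard=((0.0, 0.005),),
        other_mortality=((0.0, 0.0),),
        beta0=0.0,
        seed=0,
    )
    defaults.update(over)
    return SimConfig(**defaults)


def random_rate_arrays(rng, nbins=16, max_hazard=0.05):
    """Random per-bin hazards and mortalities for oracle-equivalence tests."""
    hazard = rng.uniform(0.0, max_hazard, nbins)
    mortality = rng.uniform(0.0, max_hazard, nbins)
    return hazard, mortality


@pytest.fixture
def toy_cohort() -> pd.DataFrame:
    """Six records, distinct event ages, for partial-likelihood oracles."""
    return pd.DataFrame({
        "study": "s1",
        "iid": np.arange(6),
        "sex": ["female"] * 6,
        "pgs": [0.5, -0.2, 1.0, 0.0, 0.3, -0.5],
        "status": ["disease", "censored", "disease", "disease",
                   "censored", "disease"],
        "exit_age": [10.0, 20.0, 30.0, 40.0, 50.0, 60.0],
    })


def naive_partial_loglik(beta, x, time, event, entry=None):
    """Breslow/Efron-free reference: no ties assumed, explicit risk sets."""
    ll = 0.0
    for i in range(len(x)):
        if not event[i]:
            continue
        t = time[i]
        denom = 0.0
        for j in range(len(x)):
            at_risk = time[j] >= t and (entry is None or entry[j] < t)
            if at_risk:
                denom += np.exp(beta * x[j])
        ll += beta * x[i] - np.log(denom)
    return ll
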