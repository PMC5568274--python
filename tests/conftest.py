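"""Shared fixtures and the independent partial-likelihood oracle.

The oracle writes out the Efron-corrected Cox partial log-likelihood for a
single binary covariate and maximizes it by 1-D numerical optimization.  It
never touches the package's fitting path, so agreement between the two is a
genuine cross-check.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from gtbias import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=2023)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort reused across design/fit tests."""
    config = SimulationConfig(n_subjects=800, seed=7)
    return config, *simulate_cohort(config)


def efron_log_partial_likelihood(
    beta: float, times: np.ndarray, events: np.ndarray, x: np.ndarray
) -> float:
    """Efron-corrected Cox partial log-likelihood, single covariate."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    x = np.asarray(x, dtype=float)
    theta = np.exp(beta * x)
    ll = 0.0
    for t in np.unique(times[events]):
        dead = events & (times == t)
        at_risk = times >= t
        d = int(dead.sum())
        risk_sum = theta[at_risk].sum()
        tied_sum = theta[dead].sum()
        ll += beta * x[dead].sum()
        for ell in range(d):
            ll -= np.log(risk_sum - (ell / d) * tied_sum)
    return ll


def brute_force_cox(
    times: np.ndarray, events: np.ndarray, x: np.ndarray
) -> float:
    """Maximize the written-out partial likelihood over a single coefficient."""
    res = minimize_scalar(
        lambda b: -efron_log_partial_likelihood(b, times, events, x),
        bounds=(-15.0, 15.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)
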