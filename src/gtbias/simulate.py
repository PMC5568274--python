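"""Discrete-time cohort simulator with guarantee-time-bias structure.

The data-generating process: N subjects are followed over ``n_intervals``
discrete periods.  A fraction of them is assigned a drug-initiation interval
W, drawn uniformly on {1, ..., n_intervals}; from interval W onward the
subject accrues a constant dose per interval, and the cumulative dose is
categorized into none/low/moderate/high groups.  At each interval the event
occurs with a logit-linear probability in the three dose-group indicators;
follow-up stops at the first event or at administrative censoring after the
last interval.

Because a subject must remain event-free up to W to become a drug user at
all — and must survive even longer to accumulate a high dose — any analysis
that attributes the full follow-up to the final exposure group inherits
guarantee-time (immortal-time) bias.  This module generates exactly that
structure so the competing analyses can be compared on it.
"""

from __future__ import annotations

from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import SimulationConfig
from .types import DoseCategory

__all__ = [
    "event_probability",
    "draw_initiation_intervals",
    "cumulative_dose",
    "dose_category",
    "dose_category_codes",
    "simulate_cohort",
]

# open-interval clamp: event_probability must stay strictly inside (0, 1)
_P_LO = np.finfo(float).tiny
_P_HI = 1.0 - np.finfo(float).epsneg

SUBJECT_COLUMNS = [
    "subject_id",
    "intended_user",
    "initiation_interval",
    "followup_end",
    "event",
    "final_dose_category",
]
LONG_COLUMNS = ["subject_id", "interval", "z1", "z2", "z3", "event_this_interval"]


def event_probability(
    z1: int,
    z2: int,
    z3: int,
    beta0: float,
    beta1: float = 0.0,
    beta2: float = 0.0,
    beta3: float = 0.0,
) -> float:
    """Per-interval event probability for a subject in a given dose group.

    Returns ``expit(beta0 + beta1*z1 + beta2*z2 + beta3*z3)``, clamped to the
    open interval (0, 1) so extreme linear predictors never produce exact 0
    or 1.  At most one of the indicators may be active.
    """
    if z1 + z2 + z3 > 1:
        raise ValueError("at most one dose-group indicator may equal 1")
    eta = beta0 + beta1 * z1 + beta2 * z2 + beta3 * z3
    return float(np.clip(expit(eta), _P_LO, _P_HI))


def draw_initiation_intervals(
    n_users: int, n_intervals: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw drug-initiation intervals, discrete uniform on {1, ..., n_intervals}."""
    if n_users < 0:
        raise ValueError("n_users must be nonnegative")
    if n_intervals < 1:
        raise ValueError("n_intervals must be positive")
    return rng.integers(1, n_intervals + 1, size=n_users)


def cumulative_dose(
    initiation_interval: Optional[int], t: int, dose_per_interval: float
) -> float:
    """Cumulative dose accrued through interval ``t`` (inclusive).

    The subject is exposed during the initiation interval itself, so a user
    with W <= t has accrued ``dose_per_interval * (t - W + 1)``.  Returns 0
    before initiation or when no initiation occurs (``None``).
    """
    if t < 1:
        raise ValueError("interval indices are 1-based")
    if initiation_interval is None or t < initiation_interval:
        return 0.0
    return dose_per_interval * (t - initiation_interval + 1)


def dose_category(
    cumdose: float, cutpoints: Tuple[float, float]
) -> DoseCategory:
    """Categorize a cumulative dose into none/low/moderate/high.

    Half-open convention: ``none`` iff the dose is exactly 0, ``low`` on
    (0, c1], ``moderate`` on (c1, c2], ``high`` above c2 — a dose landing
    exactly on a cutpoint belongs to the lower category.
    """
    c1, c2 = cutpoints
    if not c1 < c2:
        raise ValueError("cutpoints must be strictly increasing")
    if cumdose < 0:
        raise ValueError("cumulative dose cannot be negative")
    return DoseCategory(int(cumdose > 0) + int(cumdose > c1) + int(cumdose > c2))


def dose_category_codes(
    cumdose: np.ndarray, cutpoints: Tuple[float, float]
) -> np.ndarray:
    """Vectorized :func:`dose_category`; returns integer codes 0..3."""
    c1, c2 = cutpoints
    cumdose = np.asarray(cumdose)
    if (cumdose < 0).any():
        raise ValueError("cumulative dose cannot be negative")
    return (
        (cumdose > 0).astype(np.int8)
        + (cumdose > c1).astype(np.int8)
        + (cumdose > c2).astype(np.int8)
    )


def simulate_cohort(
    config: SimulationConfig,
    rng: Union[np.random.Generator, np.random.SeedSequence, None] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one cohort under the discrete-time DGP.

    Parameters
    ----------
    config:
        The data-generating parameters.
    rng:
        Optional generator (or seed sequence) overriding ``config.seed``;
        used by the Monte-Carlo harness to give each replication its own
        deterministic stream.

    Returns
    -------
    (subjects, long):
        ``subjects`` has one row per subject with columns
        ``subject_id, intended_user, initiation_interval, followup_end,
        event, final_dose_category``; ``initiation_interval`` is nullable
        (pd.NA for never-users).  ``long`` is the person-period table with
        columns ``subject_id, interval, z1, z2, z3, event_this_interval``
        and one row per subject-interval through the end of follow-up.

    Notes
    -----
    Per-interval event draws use one uniform per subject-interval over the
    full horizon and take the first crossing; this is distributionally
    identical to drawing sequentially and stopping, and is deterministic
    given the seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif isinstance(rng, np.random.SeedSequence):
        rng = np.random.default_rng(rng)

    n = config.n_subjects
    n_periods = config.n_intervals
    d = config.n_intended_users

    intended = np.zeros(n, dtype=bool)
    if d > 0:
        intended[rng.choice(n, size=d, replace=False)] = True
    # W = 0 encodes "never initiates"
    w = np.zeros(n, dtype=np.int64)
    w[intended] = draw_initiation_intervals(d, n_periods, rng)

    t_grid = np.arange(1, n_periods + 1)
    exposed = intended[:, None] & (t_grid[None, :] >= w[:, None])
    periods_on_drug = np.where(exposed, t_grid[None, :] - w[:, None] + 1, 0)
    cumdose = periods_on_drug * config.dose_per_interval
    codes = dose_category_codes(cumdose, config.dose_cutpoints)  # (n, T)

    p_by_code = np.clip(
        expit(
            config.beta0
            + np.array([0.0, config.beta1, config.beta2, config.beta3])
        ),
        _P_LO,
        _P_HI,
    )
    hit = rng.random((n, n_periods)) < p_by_code[codes]

    any_event = hit.any(axis=1)
    first_hit = hit.argmax(axis=1)  # 0 when no event; guarded by any_event
    followup_end = np.where(any_event, first_hit + 1, n_periods)
    subject_ids = np.arange(1, n + 1, dtype=np.int64)
    final_code = codes[np.arange(n), followup_end - 1]

    subjects = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "intended_user": intended,
            "initiation_interval": pd.array(
                np.where(intended, w, -1), dtype="Int64"
            ),
            "followup_end": followup_end.astype(np.int64),
            "event": any_event,
            "final_dose_category": pd.Categorical.from_codes(
                final_code, categories=[c.label for c in DoseCategory]
            ),
        }
    )
    subjects.loc[~subjects["intended_user"], "initiation_interval"] = pd.NA

    # long table: subject i contributes intervals 1..followup_end
    lengths = followup_end
    total = int(lengths.sum())
    sid_long = np.repeat(subject_ids, lengths)
    row_idx = np.repeat(np.arange(n), lengths)
    offsets = np.repeat(np.cumsum(lengths) - lengths, lengths)
    t_long = np.arange(total) - offsets + 1
    code_long = codes[row_idx, t_long - 1]
    event_long = (t_long == followup_end[row_idx]) & any_event[row_idx]

    long = pd.DataFrame(
        {
            "subject_id": sid_long,
            "interval": t_long.astype(np.int64),
            "z1": (code_long == 1).astype(np.int8),
            "z2": (code_long == 2).astype(np.int8),
            "z3": (code_long == 3).astype(np.int8),
            "event_this_interval": event_long,
        }
    )
    return subjects, long
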