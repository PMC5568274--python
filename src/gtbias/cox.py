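"""Cox proportional-hazards fitting for the three designs.

The partial-likelihood maximization is delegated to lifelines
(:class:`~lifelines.CoxPHFitter` for time-fixed designs,
:class:`~lifelines.CoxTimeVaryingFitter` for (start, stop] counting-process
designs), both with Efron's tie correction — the appropriate choice here
because discrete event times produce heavy ties.

Dose groups that cannot be estimated — no subject ever occupies the group,
the indicator is constant, or the group contributes no events (a monotone
partial likelihood) — are detected up front, removed from the model and
reported in :attr:`FitResult.non_estimable` instead of being returned as
numbers.  Their person-time remains in the risk sets under the reference
coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, CoxTimeVaryingFitter
from lifelines.exceptions import ConvergenceError
from scipy.stats import norm

from .exceptions import DataError, FitError

__all__ = ["GroupEstimate", "FitResult", "fit_cox"]

#: default covariate columns, in dose-group order
_DEFAULT_COVARIATES = ("z1", "z2", "z3")
#: display names for the default indicators
_GROUP_OF = {"z1": "low", "z2": "moderate", "z3": "high", "user": "user"}


@dataclass(frozen=True)
class GroupEstimate:
    """Estimate for one dose group: log HR, its SE, Wald test and HR."""

    log_hr: float
    se: float
    wald_z: float
    p_value: float

    @property
    def hr(self) -> float:
        return float(np.exp(self.log_hr))


@dataclass
class FitResult:
    """Outcome of one Cox fit.

    ``estimates`` maps group labels (``low``/``moderate``/``high``, or
    ``user`` for the binary landmark coding) to their Wald summaries;
    groups listed in ``non_estimable`` were dropped before fitting.
    """

    estimates: Dict[str, GroupEstimate]
    non_estimable: Tuple[str, ...]
    n_subjects_used: int
    n_events_used: int
    converged: bool
    diagnostics: str = ""
    warnings: Tuple[str, ...] = field(default_factory=tuple)

    def hr(self, group: str) -> float:
        return self.estimates[group].hr


def _screen_columns(
    df: pd.DataFrame, covariates: Sequence[str], event: np.ndarray
) -> Tuple[list, list]:
    """Split covariates into estimable and non-estimable ones."""
    usable, dropped = [], []
    for col in covariates:
        x = df[col].to_numpy()
        if x.min() == x.max():  # constant column: no contrast
            dropped.append(col)
        elif not event[x == 1].any():  # no events in group: monotone likelihood
            dropped.append(col)
        elif not event[x == 0].any():  # no events outside the group
            dropped.append(col)
        else:
            usable.append(col)
    return usable, dropped


def fit_cox(
    design: pd.DataFrame,
    covariates: Optional[Sequence[str]] = None,
) -> FitResult:
    """Fit a Cox model to a time-fixed or counting-process design.

    The design format is inferred from the columns: a ``time`` column means
    a baseline-coded table (one row per subject), ``start``/``stop`` columns
    mean counting-process rows.  Wald z statistics and two-sided p-values
    are reported per coefficient.

    Raises
    ------
    FitError
        If the design contains no events.
    DataError
        If the columns match neither format.
    """
    if covariates is None:
        covariates = [
            c for c in (*_DEFAULT_COVARIATES, "user") if c in design.columns
        ]
    if not covariates:
        raise DataError("design has no recognized covariate columns")

    time_fixed = "time" in design.columns
    if not time_fixed and not {"start", "stop"} <= set(design.columns):
        raise DataError(
            "design must have either a 'time' column or 'start'/'stop' columns"
        )

    event = design["event"].to_numpy(dtype=bool)
    n_events = int(event.sum())
    if "subject_id" in design.columns:
        n_subjects = int(design["subject_id"].nunique())
    else:
        n_subjects = len(design) if time_fixed else 0
    if n_events == 0:
        raise FitError("cannot fit a Cox model to a design with no events")

    usable, dropped = _screen_columns(design, covariates, event)
    labels = {c: _GROUP_OF.get(c, c) for c in covariates}
    non_estimable = tuple(labels[c] for c in dropped)
    if not usable:
        return FitResult(
            estimates={},
            non_estimable=non_estimable,
            n_subjects_used=n_subjects,
            n_events_used=n_events,
            converged=True,
            diagnostics="no estimable covariates",
        )

    caught: list = []
    try:
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            # tight solver precision: flat partial likelihoods (few events)
            # otherwise stop Newton-Raphson before the coefficient settles
            fit_options = {"precision": 1e-14, "r_precision": 1e-16}
            if time_fixed:
                fitter = CoxPHFitter()
                fitter.fit(
                    design[["time", "event", *usable]],
                    duration_col="time",
                    event_col="event",
                    fit_options=fit_options,
                )
            else:
                fitter = CoxTimeVaryingFitter()
                fitter.fit(
                    design[["subject_id", "start", "stop", "event", *usable]],
                    id_col="subject_id",
                    start_col="start",
                    stop_col="stop",
                    event_col="event",
                    fit_options=fit_options,
                )
        caught = [str(w.message) for w in wlist]
    except ConvergenceError as err:
        return FitResult(
            estimates={},
            non_estimable=non_estimable,
            n_subjects_used=n_subjects,
            n_events_used=n_events,
            converged=False,
            diagnostics=f"partial-likelihood maximization failed: {err}",
            warnings=tuple(caught),
        )

    params = fitter.params_
    ses = fitter.standard_errors_
    estimates = {}
    for col in usable:
        beta = float(params[col])
        se = float(ses[col])
        z = beta / se
        p = float(2.0 * norm.sf(abs(z)))
        estimates[labels[col]] = GroupEstimate(
            log_hr=beta, se=se, wald_z=z, p_value=p
        )
    return FitResult(
        estimates=estimates,
        non_estimable=non_estimable,
        n_subjects_used=n_subjects,
        n_events_used=n_events,
        converged=True,
        warnings=tuple(caught),
    )
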