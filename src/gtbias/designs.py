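"""Design builders for the three competing analyses.

Each builder turns the simulator's (subjects, long) tables into the data
layout one analysis strategy would fit:

* :func:`make_naive_design` — time-fixed Cox with the subject's *final*
  dose category applied from time 0.  This deliberately reproduces the
  guarantee-time-biased design: all the event-free time a subject needed to
  accumulate dose is credited to the exposed state.
* :func:`make_counting_process` — (start, stop] rows with the dose group as
  a time-dependent covariate, the standard counting-process expansion that
  removes the bias.
* :func:`make_landmark_design` — time-fixed Cox on the sub-cohort still
  event-free at a landmark time tau, with exposure frozen at its value at
  tau and the clock restarted there.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import DataError
from .types import DoseCategory

__all__ = [
    "make_naive_design",
    "make_counting_process",
    "make_landmark_design",
]

_CAT_TO_CODE = {c.label: int(c) for c in DoseCategory}


def make_naive_design(subjects: pd.DataFrame) -> pd.DataFrame:
    """One row per subject: full follow-up attributed to the final category.

    Returns columns ``subject_id, time, event, z1, z2, z3`` where time is
    the end of follow-up and the indicators are fixed at the subject's
    end-of-follow-up dose category.
    """
    if len(subjects) == 0:
        raise DataError("cannot build a design from an empty cohort")
    code = (
        subjects["final_dose_category"].astype(str).map(_CAT_TO_CODE).to_numpy()
    )
    return pd.DataFrame(
        {
            "subject_id": subjects["subject_id"].to_numpy(),
            "time": subjects["followup_end"].to_numpy(dtype=float),
            "event": subjects["event"].to_numpy(dtype=bool),
            "z1": (code == 1).astype(np.int8),
            "z2": (code == 2).astype(np.int8),
            "z3": (code == 3).astype(np.int8),
        }
    )


def make_counting_process(long: pd.DataFrame) -> pd.DataFrame:
    """Collapse the person-period table into merged (start, stop] rows.

    Consecutive intervals with identical dose-group indicators are merged
    into a single row with ``start`` = first interval - 1 and ``stop`` =
    last interval; the event flag is carried on the final row of subjects
    with events.  Total person-time is preserved.
    """
    if len(long) == 0:
        raise DataError("cannot build a design from an empty long table")
    long = long.sort_values(["subject_id", "interval"], kind="stable")
    sid = long["subject_id"].to_numpy()
    t = long["interval"].to_numpy()
    ev = long["event_this_interval"].to_numpy(dtype=bool)
    code = (
        long["z1"].to_numpy() * 1
        + long["z2"].to_numpy() * 2
        + long["z3"].to_numpy() * 3
    )
    if (long[["z1", "z2", "z3"]].to_numpy().sum(axis=1) > 1).any():
        raise DataError("more than one dose-group indicator active in a row")

    new_subject = np.r_[True, sid[1:] != sid[:-1]]
    if (t[new_subject] != 1).any():
        raise DataError("each subject's intervals must start at 1")
    contiguous = t[1:] == t[:-1] + 1
    if (~(new_subject[1:] | contiguous)).any():
        raise DataError("overlapping or non-contiguous intervals in long table")
    last_of_subject = np.r_[new_subject[1:], True]
    if (ev & ~last_of_subject).any():
        raise DataError("event rows must terminate the subject's follow-up")

    brk = new_subject | np.r_[True, code[1:] != code[:-1]]
    brk[0] = True
    group_end = np.r_[brk[1:], True]
    start = t[brk] - 1.0
    stop = t[group_end].astype(float)
    grp_code = code[brk]
    return pd.DataFrame(
        {
            "subject_id": sid[brk],
            "start": start,
            "stop": stop,
            "z1": (grp_code == 1).astype(np.int8),
            "z2": (grp_code == 2).astype(np.int8),
            "z3": (grp_code == 3).astype(np.int8),
            "event": ev[group_end],
        }
    )


def make_landmark_design(
    subjects: pd.DataFrame,
    long: pd.DataFrame,
    tau: int,
    n_intervals: int | None = None,
    coding: str = "dose_groups",
) -> pd.DataFrame:
    """Landmark design: condition on being event-free at ``tau``.

    Subjects with ``followup_end <= tau`` (event or censoring at or before
    the landmark) are excluded.  Exposure is frozen at the dose category
    held during interval ``tau`` — equivalently, the category of the
    cumulative dose accrued through tau — and analysis time restarts at the
    landmark (``time = followup_end - tau``).

    ``coding="dose_groups"`` (default) keeps the three indicators;
    ``coding="binary"`` collapses them to a single ``user`` indicator
    I(W <= tau), the landmark drug-use variable Z(tau).
    """
    if coding not in ("dose_groups", "binary"):
        raise ValueError(f"unknown landmark coding: {coding!r}")
    if n_intervals is None:
        n_intervals = int(long["interval"].max())
    if not 0 < tau < n_intervals:
        raise ValueError(
            f"landmark time must lie strictly inside (0, {n_intervals})"
        )
    keep = subjects["followup_end"] > tau
    if not keep.any():
        raise DataError(f"no subjects remain at risk past the landmark tau={tau}")
    kept = subjects.loc[keep, ["subject_id", "followup_end", "event"]]

    at_tau = long.loc[long["interval"] == tau, ["subject_id", "z1", "z2", "z3"]]
    design = kept.merge(at_tau, on="subject_id", how="left", validate="1:1")
    # every kept subject was under observation at tau, so the merge is total
    if design[["z1", "z2", "z3"]].isna().any().any():
        raise DataError("long table lacks rows at the landmark interval")

    design["time"] = (design.pop("followup_end") - tau).astype(float)
    design["event"] = design["event"].astype(bool)
    if coding == "binary":
        design["user"] = (
            design.pop("z1") + design.pop("z2") + design.pop("z3")
        ).astype(np.int8)
        return design[["subject_id", "time", "event", "user"]]
    design[["z1", "z2", "z3"]] = design[["z1", "z2", "z3"]].astype(np.int8)
    return design[["subject_id", "time", "event", "z1", "z2", "z3"]]
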