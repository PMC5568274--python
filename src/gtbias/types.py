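"""Core record types shared across the simulator, design builders and IO.

The package moves data around as pandas DataFrames with documented column
schemas (see :mod:`gtbias.io`); the dataclasses here define the per-row
meaning of those schemas and are used where single records are constructed
or validated.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Optional


class DoseCategory(IntEnum):
    """Cumulative-dose exposure group.

    ``NONE`` covers both never-users and subjects whose event preceded drug
    initiation (a realized non-user). The ordering reflects that cumulative
    dose only grows: a subject's category is nondecreasing over follow-up.
    """

    NONE = 0
    LOW = 1
    MODERATE = 2
    HIGH = 3

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "DoseCategory":
        try:
            return cls[label.upper()]
        except KeyError:
            raise ValueError(f"unknown dose category label: {label!r}") from None


#: dose-group labels in indicator order (z1, z2, z3)
GROUP_LABELS = ("low", "moderate", "high")


@dataclass(frozen=True)
class SubjectRecord:
    """One subject of a (simulated or imported) cohort.

    ``initiation_interval`` is the 1-based interval W in which drug use
    starts, or ``None`` for never-users. ``final_dose_category`` is the
    category realized at the end of follow-up; a subject whose event occurs
    before W is a realized non-user even if drug use was intended.
    """

    subject_id: int
    intended_user: bool
    initiation_interval: Optional[int]
    followup_end: int
    event: bool
    final_dose_category: DoseCategory

    def __post_init__(self) -> None:
        if not self.intended_user and self.initiation_interval is not None:
            raise ValueError("non-user cannot have an initiation interval")
        if self.followup_end < 1:
            raise ValueError("followup_end must be >= 1")


@dataclass(frozen=True)
class CohortLongRow:
    """One subject-interval of the long (person-period) table."""

    subject_id: int
    interval: int
    z1: int
    z2: int
    z3: int
    event_this_interval: bool

    def __post_init__(self) -> None:
        if self.z1 + self.z2 + self.z3 > 1:
            raise ValueError("at most one dose-group indicator may be active")
        if self.interval < 1:
            raise ValueError("interval indices are 1-based")


@dataclass(frozen=True)
class CountingProcessRow:
    """A (start, stop] interval with interval-constant covariates."""

    subject_id: int
    start: float
    stop: float
    z1: int
    z2: int
    z3: int
    event: bool

    def __post_init__(self) -> None:
        if not self.start < self.stop:
            raise ValueError("counting-process rows need start < stop")
        if self.z1 + self.z2 + self.z3 > 1:
            raise ValueError("at most one dose-group indicator may be active")
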