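"""Simulation configuration: the tunable parameters of the data-generating
process, with validation and flat-dict (de)serialization."""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Tuple

from .exceptions import ConfigurationError

#: default low/moderate and moderate/high cumulative-dose boundaries.  With a
#: dose of 0.5 per interval over a 10-interval horizon these split the
#: attainable range (0, 5] into 1-3, 4-6 and 7-10 exposed intervals.
DEFAULT_CUTPOINTS: Tuple[float, float] = (1.5, 3.0)

#: baseline per-interval log-odds of disease used throughout the simulation
#: study (per-interval event probability 0.015/1.015 ~ 1.48%).
DEFAULT_BETA0 = math.log(0.015)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the discrete-time cohort data-generating process.

    Parameters
    ----------
    n_subjects:
        Total cohort size N.
    intended_user_rate:
        Proportion of subjects assigned a drug-initiation time, in (0, 1).
        Subjects whose event precedes initiation end up as realized
        non-users, so the realized user fraction is at most this rate.
    n_intervals:
        Number of discrete follow-up intervals (years); administrative
        censoring occurs at the end of the last one.
    dose_per_interval:
        Constant dose accrued during each exposed interval.
    beta0:
        Log-odds intercept of the per-interval event probability.
    beta1, beta2, beta3:
        Log-odds effects of the low / moderate / high cumulative-dose
        groups.  All zero under the null of no drug effect.
    dose_cutpoints:
        Strictly increasing boundaries (c1, c2) between low/moderate and
        moderate/high cumulative dose; ties go to the lower category.
    seed:
        Root seed for the pseudo-random generator.
    """

    n_subjects: int = 5000
    intended_user_rate: float = 0.05
    n_intervals: int = 10
    dose_per_interval: float = 0.5
    beta0: float = DEFAULT_BETA0
    beta1: float = 0.0
    beta2: float = 0.0
    beta3: float = 0.0
    dose_cutpoints: Tuple[float, float] = DEFAULT_CUTPOINTS
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "dose_cutpoints", tuple(self.dose_cutpoints))
        if not (isinstance(self.n_subjects, int) and self.n_subjects >= 1):
            raise ConfigurationError("n_subjects must be a positive integer")
        if not 0.0 < self.intended_user_rate < 1.0:
            raise ConfigurationError("intended_user_rate must lie in (0, 1)")
        if not (isinstance(self.n_intervals, int) and self.n_intervals >= 1):
            raise ConfigurationError("n_intervals must be a positive integer")
        if not self.dose_per_interval > 0:
            raise ConfigurationError("dose_per_interval must be positive")
        for name in ("beta0", "beta1", "beta2", "beta3"):
            if not math.isfinite(getattr(self, name)):
                raise ConfigurationError(f"{name} must be a finite real number")
        c = self.dose_cutpoints
        if len(c) != 2 or not (0 < c[0] < c[1]):
            raise ConfigurationError(
                "dose_cutpoints must be two strictly increasing positive values"
            )
        if not c[1] < self.n_intervals * self.dose_per_interval:
            raise ConfigurationError(
                "dose_cutpoints must lie below the maximum attainable "
                "cumulative dose n_intervals * dose_per_interval"
            )
        if not isinstance(self.seed, int):
            raise ConfigurationError("seed must be an integer")

    @property
    def n_intended_users(self) -> int:
        """Number of subjects assigned an initiation time, round(N * rate)."""
        return round(self.n_subjects * self.intended_user_rate)

    @property
    def betas(self) -> Tuple[float, float, float, float]:
        return (self.beta0, self.beta1, self.beta2, self.beta3)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dose_cutpoints"] = list(self.dose_cutpoints)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        """Build a config from a flat mapping; unknown keys are rejected."""
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(
                f"unknown configuration key(s): {', '.join(sorted(unknown))}"
            )
        kwargs = dict(data)
        if "dose_cutpoints" in kwargs:
            try:
                kwargs["dose_cutpoints"] = tuple(
                    float(x) for x in kwargs["dose_cutpoints"]
                )
            except (TypeError, ValueError):
                raise ConfigurationError(
                    "dose_cutpoints must be a pair of numbers"
                ) from None
        for field in dataclasses.fields(cls):
            if field.name in kwargs and field.name in (
                "n_subjects",
                "n_intervals",
                "seed",
            ):
                value = kwargs[field.name]
                if isinstance(value, float) and not value.is_integer():
                    raise ConfigurationError(f"{field.name} must be an integer")
                kwargs[field.name] = int(value)
        return cls(**kwargs)

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)
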