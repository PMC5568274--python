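"""CSV schemas, configuration files, logging and run manifests.

File formats
------------
Subject table CSV (one row per subject)::

    subject_id,intended_user,initiation_interval,followup_end,event,final_dose_category

``initiation_interval`` is empty for never-users; booleans are written as
``True``/``False``; ``final_dose_category`` is one of none/low/moderate/high.

Counting-process CSV (merged (start, stop] rows, half-open on the left)::

    subject_id,start,stop,z1,z2,z3,event

User cohort CSV (for applying the estimators to external data)::

    subject_id,followup_years,event,drug_start_year,yearly_dose

Years are 1-based interval indices on the same discrete grid as the
simulator; ``drug_start_year`` is empty for never-users; ``yearly_dose`` is
the dose accrued during each year on the drug, so the cumulative dose at
year t is ``yearly_dose * (t - drug_start_year + 1)``.

Configuration files are flat YAML key/value mappings of
:class:`~gtbias.config.SimulationConfig` and
:class:`~gtbias.evaluation.ScenarioSpec` fields; unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .config import SimulationConfig
from .evaluation import SEED_DERIVATION_RULE, ScenarioSpec
from .exceptions import ConfigurationError, DataError
from .simulate import LONG_COLUMNS, SUBJECT_COLUMNS, dose_category_codes
from .types import DoseCategory

__all__ = [
    "load_config",
    "load_scenario_spec",
    "save_config",
    "write_subjects_csv",
    "read_subjects_csv",
    "write_counting_csv",
    "read_counting_csv",
    "write_long_csv",
    "read_long_csv",
    "read_cohort_csv",
    "RunManifest",
    "write_manifest",
    "load_manifest",
    "setup_logging",
]

logger = logging.getLogger("gtbias")

COUNTING_COLUMNS = ["subject_id", "start", "stop", "z1", "z2", "z3", "event"]
COHORT_CSV_COLUMNS = [
    "subject_id",
    "followup_years",
    "event",
    "drug_start_year",
    "yearly_dose",
]


def setup_logging(verbose: bool = False, logfile: Optional[str] = None) -> None:
    """Route package logs to stderr (and optionally a file)."""
    handlers: list = [logging.StreamHandler(sys.stderr)]
    if logfile:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


# -- configuration files ---------------------------------------------------


def _load_yaml_mapping(path: Union[str, Path]) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"configuration file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as err:
        raise ConfigurationError(f"cannot parse {path}: {err}") from err
    if not isinstance(data, dict):
        raise ConfigurationError(
            f"{path} must contain a flat key/value mapping"
        )
    return data


def load_config(path: Union[str, Path]) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a flat YAML file."""
    config = SimulationConfig.from_dict(_load_yaml_mapping(path))
    logger.info("effective configuration: %s", config.to_dict())
    return config


def load_scenario_spec(path: Union[str, Path]) -> ScenarioSpec:
    """Load a :class:`ScenarioSpec` (scenario + simulation keys merged)."""
    spec = ScenarioSpec.from_dict(_load_yaml_mapping(path))
    logger.info("effective scenario: %s", spec.to_dict())
    return spec


def save_config(
    obj: Union[SimulationConfig, ScenarioSpec], path: Union[str, Path]
) -> None:
    Path(path).write_text(yaml.safe_dump(obj.to_dict(), sort_keys=True))


# -- simulator tables ------------------------------------------------------


def write_subjects_csv(subjects: pd.DataFrame, path: Union[str, Path]) -> None:
    subjects.to_csv(path, index=False, columns=SUBJECT_COLUMNS)


def read_subjects_csv(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SUBJECT_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(
            f"subject table missing column(s): {', '.join(sorted(missing))}"
        )
    df["intended_user"] = df["intended_user"].astype(bool)
    df["event"] = df["event"].astype(bool)
    df["initiation_interval"] = df["initiation_interval"].astype("Int64")
    df["final_dose_category"] = pd.Categorical(
        df["final_dose_category"], categories=[c.label for c in DoseCategory]
    )
    if df["final_dose_category"].isna().any():
        raise DataError("unknown final_dose_category label in subject table")
    return df[SUBJECT_COLUMNS]


def write_counting_csv(counting: pd.DataFrame, path: Union[str, Path]) -> None:
    counting.to_csv(path, index=False, columns=COUNTING_COLUMNS)


def read_counting_csv(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COUNTING_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(
            f"counting-process table missing column(s): {', '.join(sorted(missing))}"
        )
    df["event"] = df["event"].astype(bool)
    for c in ("z1", "z2", "z3"):
        df[c] = df[c].astype(np.int8)
    if (df["start"] >= df["stop"]).any():
        raise DataError("counting-process rows need start < stop")
    return df[COUNTING_COLUMNS]


def write_long_csv(long: pd.DataFrame, path: Union[str, Path]) -> None:
    long.to_csv(path, index=False, columns=LONG_COLUMNS)


def read_long_csv(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(LONG_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(
            f"long table missing column(s): {', '.join(sorted(missing))}"
        )
    df["event_this_interval"] = df["event_this_interval"].astype(bool)
    for c in ("z1", "z2", "z3"):
        df[c] = df[c].astype(np.int8)
    return df[LONG_COLUMNS]


# -- user cohort CSV -------------------------------------------------------


def read_cohort_csv(
    path: Union[str, Path],
    cutpoints: Tuple[float, float],
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Read an external cohort and derive the subject and long tables.

    Per-year doses are converted to cumulative doses, then to dose
    categories via the supplied ``cutpoints`` (e.g. cumulative milligram
    boundaries).  A subject whose event precedes the recorded drug start is
    a realized non-user.  Returns the same (subjects, long) pair as
    :func:`~gtbias.simulate.simulate_cohort`.
    """
    df = pd.read_csv(path)
    missing = set(COHORT_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(
            f"cohort CSV missing column(s): {', '.join(sorted(missing))}"
        )
    if len(df) == 0:
        raise DataError("cohort CSV contains a header but no data rows")
    c1, c2 = cutpoints
    if not c1 < c2:
        raise ConfigurationError("cutpoints must be strictly increasing")

    subjects_rows = []
    long_frames = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        try:
            followup = int(row.followup_years)
            if followup < 1:
                raise ValueError("followup_years must be >= 1")
            event = bool(int(row.event))
            has_start = not pd.isna(row.drug_start_year)
            start = int(row.drug_start_year) if has_start else None
            if has_start and start < 1:
                raise ValueError("drug_start_year must be >= 1")
            yearly = float(row.yearly_dose) if not pd.isna(row.yearly_dose) else 0.0
            if yearly < 0:
                raise ValueError("yearly_dose cannot be negative")
        except (TypeError, ValueError) as err:
            raise DataError(f"cohort CSV line {i}: {err}") from None

        t = np.arange(1, followup + 1)
        if has_start and yearly > 0:
            exposed_years = np.where(t >= start, t - start + 1, 0)
        else:
            exposed_years = np.zeros_like(t)
        cum = exposed_years * yearly
        codes = dose_category_codes(cum, (c1, c2))
        final_code = int(codes[-1])
        subjects_rows.append(
            {
                "subject_id": row.subject_id,
                "intended_user": has_start,
                "initiation_interval": start if has_start else pd.NA,
                "followup_end": followup,
                "event": event,
                "final_dose_category": DoseCategory(final_code).label,
            }
        )
        long_frames.append(
            pd.DataFrame(
                {
                    "subject_id": row.subject_id,
                    "interval": t,
                    "z1": (codes == 1).astype(np.int8),
                    "z2": (codes == 2).astype(np.int8),
                    "z3": (codes == 3).astype(np.int8),
                    "event_this_interval": (t == followup) & event,
                }
            )
        )

    subjects = pd.DataFrame(subjects_rows)
    subjects["initiation_interval"] = subjects["initiation_interval"].astype(
        "Int64"
    )
    subjects["final_dose_category"] = pd.Categorical(
        subjects["final_dose_category"],
        categories=[c.label for c in DoseCategory],
    )
    long = pd.concat(long_frames, ignore_index=True)
    return subjects, long


# -- run manifests ---------------------------------------------------------


@dataclass
class RunManifest:
    """Provenance record written *before* results, sufficient to re-run."""

    scenario: dict
    root_seed: int
    seed_derivation: str = SEED_DERIVATION_RULE
    created_utc: str = field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat()
    )
    package_version: str = _pkg_version
    outputs: List[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def write_manifest(manifest: RunManifest, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(manifest.to_dict(), indent=2) + "\n")


def load_manifest(path: Union[str, Path]) -> RunManifest:
    data = json.loads(Path(path).read_text())
    return RunManifest(**data)
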