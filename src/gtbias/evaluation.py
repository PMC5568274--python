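"""Monte-Carlo harness comparing the three analyses on simulated cohorts.

For each replication a fresh cohort is simulated, every requested design is
built and fitted, and the per-group hazard ratios and Wald p-values are
recorded.  Aggregation yields, per method and dose group: the rejection
count at level alpha (type I error under the null, power under an
alternative), the mean estimated hazard ratio, its bias against the true
hazard ratio, and the mean squared error.

Bias and MSE are computed on the hazard-ratio scale: bias = mean(HR_hat) -
HR_true and MSE = mean((HR_hat - HR_true)^2), over the replications in
which the group was estimable.  Replications where a group has no exposed
subjects or no events are excluded from that group's aggregates and counted
in ``n_non_estimable``.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import SimulationConfig
from .cox import fit_cox
from .designs import make_counting_process, make_landmark_design, make_naive_design
from .exceptions import ConfigurationError, DataError, FitError
from .simulate import simulate_cohort
from .types import GROUP_LABELS

__all__ = [
    "ScenarioSpec",
    "CellResult",
    "ScenarioResult",
    "implied_hazard_ratios",
    "run_scenario",
    "tabulate",
    "plot_rejection_rates",
]

logger = logging.getLogger("gtbias")

#: canonical method keys, in presentation order
METHODS = ("naive_cox", "timedep_cox", "landmark")

#: how per-replication seeds are derived from the root seed (recorded in the
#: run manifest so a re-run can reproduce every replication exactly)
SEED_DERIVATION_RULE = "numpy.random.SeedSequence(root_seed).spawn(n_replications)"


def implied_hazard_ratios(config: SimulationConfig) -> Dict[str, float]:
    """True continuous-time hazard ratios implied by the generating betas.

    The discrete-time model sets the per-interval event probability p_g by a
    logit link; the equivalent continuous-time hazard over an interval is
    -log(1 - p_g), so the true hazard ratio of group g versus non-users is
    log(1 - p_g) / log(1 - p_0).  Under the null (all group betas zero) this
    is exactly 1 for every group.
    """
    p0 = expit(config.beta0)
    out = {}
    for label, beta in zip(
        GROUP_LABELS, (config.beta1, config.beta2, config.beta3)
    ):
        pg = expit(config.beta0 + beta)
        out[label] = math.log1p(-pg) / math.log1p(-p0)
    return out


@dataclass(frozen=True)
class ScenarioSpec:
    """One Monte-Carlo scenario: a DGP plus the analyses to run on it."""

    config: SimulationConfig
    n_replications: int = 1000
    alpha: float = 0.05
    methods: Tuple[str, ...] = METHODS
    landmark_times: Tuple[int, ...] = (5, 7)
    landmark_coding: str = "dose_groups"
    true_hr: Optional[Dict[str, float]] = None

    def __post_init__(self) -> None:
        if not (isinstance(self.n_replications, int) and self.n_replications >= 1):
            raise ConfigurationError("n_replications must be a positive integer")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must lie in (0, 1)")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ConfigurationError(
                f"unknown method(s): {', '.join(sorted(unknown))}"
            )
        if not self.methods:
            raise ConfigurationError("at least one method must be requested")
        object.__setattr__(self, "methods", tuple(self.methods))
        object.__setattr__(
            self, "landmark_times", tuple(int(t) for t in self.landmark_times)
        )
        for tau in self.landmark_times:
            if not 0 < tau < self.config.n_intervals:
                raise ConfigurationError(
                    f"landmark time {tau} outside (0, {self.config.n_intervals})"
                )
        if self.landmark_coding not in ("dose_groups", "binary"):
            raise ConfigurationError(
                f"unknown landmark_coding: {self.landmark_coding!r}"
            )
        if self.true_hr is None:
            object.__setattr__(
                self, "true_hr", implied_hazard_ratios(self.config)
            )

    @property
    def method_keys(self) -> Tuple[str, ...]:
        """Expanded method columns: one per landmark time."""
        keys = []
        for m in self.methods:
            if m == "landmark":
                keys.extend(f"landmark_{tau}" for tau in self.landmark_times)
            else:
                keys.append(m)
        return tuple(keys)

    def groups_for(self, method_key: str) -> Tuple[str, ...]:
        if method_key.startswith("landmark_") and self.landmark_coding == "binary":
            return ("user",)
        return GROUP_LABELS

    def to_dict(self) -> dict:
        d = {
            "n_replications": self.n_replications,
            "alpha": self.alpha,
            "methods": list(self.methods),
            "landmark_times": list(self.landmark_times),
            "landmark_coding": self.landmark_coding,
        }
        d.update(self.config.to_dict())
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioSpec":
        """Build from a flat mapping (scenario + simulation keys merged)."""
        data = dict(data)
        own = {}
        for key in (
            "n_replications",
            "alpha",
            "methods",
            "landmark_times",
            "landmark_coding",
            "true_hr",
        ):
            if key in data:
                own[key] = data.pop(key)
        if "methods" in own:
            own["methods"] = tuple(own["methods"])
        if "n_replications" in own:
            own["n_replications"] = int(own["n_replications"])
        config = SimulationConfig.from_dict(data)
        return cls(config=config, **own)


@dataclass
class CellResult:
    """Aggregated Monte-Carlo metrics for one method x dose group."""

    method: str
    group: str
    n_replications: int
    n_estimable: int
    rejection_count: int
    mean_hr: float
    bias: float
    mse: float

    @property
    def estimable(self) -> bool:
        return self.n_estimable > 0

    @property
    def rejection_rate(self) -> float:
        if self.n_estimable == 0:
            return float("nan")
        return self.rejection_count / self.n_estimable

    @property
    def hr_sd(self) -> float:
        """Across-replication SD of the HR estimate, sqrt(mse - bias^2)."""
        if self.n_estimable == 0:
            return float("nan")
        return math.sqrt(max(self.mse - self.bias**2, 0.0))

    @property
    def mc_se(self) -> float:
        """Monte-Carlo standard error of the mean HR (hence of the bias)."""
        if self.n_estimable == 0:
            return float("nan")
        return self.hr_sd / math.sqrt(self.n_estimable)


@dataclass
class ScenarioResult:
    """All cells of one scenario, plus the spec that produced them."""

    spec: ScenarioSpec
    cells: Dict[Tuple[str, str], CellResult]
    n_not_converged: int = 0

    def cell(self, method: str, group: str) -> CellResult:
        return self.cells[(method, group)]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "beta0_label": beta0_label(self.spec.config.beta0),
                "method": c.method,
                "group": c.group,
                "n_replications": c.n_replications,
                "n_estimable": c.n_estimable,
                "rejection_count": c.rejection_count,
                "mean_hr": c.mean_hr,
                "bias": c.bias,
                "mse": c.mse,
            }
            for c in self.cells.values()
        ]
        return pd.DataFrame(rows)


def beta0_label(beta0: float) -> str:
    """Human-readable label log(p) for a log-odds intercept."""
    return f"log({math.exp(beta0):.6g})"


def _fit_one_method(subjects, long, method_key, spec):
    """Build the design for one method key and fit it; returns a FitResult."""
    if method_key == "naive_cox":
        design = make_naive_design(subjects)
    elif method_key == "timedep_cox":
        design = make_counting_process(long)
    else:
        tau = int(method_key.split("_", 1)[1])
        design = make_landmark_design(
            subjects,
            long,
            tau,
            n_intervals=spec.config.n_intervals,
            coding=spec.landmark_coding,
        )
    return fit_cox(design)


def run_scenario(spec: ScenarioSpec, progress_every: int = 100) -> ScenarioResult:
    """Run all replications of a scenario and aggregate per method x group.

    Deterministic given ``spec.config.seed``: replication r uses the r-th
    child of ``SeedSequence(seed)``, so any replication can be reproduced in
    isolation.
    """
    method_keys = spec.method_keys
    hrs: Dict[Tuple[str, str], list] = {
        (m, g): [] for m in method_keys for g in spec.groups_for(m)
    }
    rejections: Dict[Tuple[str, str], int] = {k: 0 for k in hrs}
    n_not_converged = 0

    children = np.random.SeedSequence(spec.config.seed).spawn(
        spec.n_replications
    )
    logger.info(
        "scenario start: beta0=%s, N=%d, %d replications, methods=%s",
        beta0_label(spec.config.beta0),
        spec.config.n_subjects,
        spec.n_replications,
        ",".join(method_keys),
    )
    for r, child in enumerate(children):
        subjects, long = simulate_cohort(spec.config, rng=child)
        for m in method_keys:
            try:
                result = _fit_one_method(subjects, long, m, spec)
            except (FitError, DataError) as err:
                logger.debug("replication %d, %s: %s", r, m, err)
                continue
            if not result.converged:
                n_not_converged += 1
                continue
            for g in spec.groups_for(m):
                est = result.estimates.get(g)
                if est is None:
                    continue
                hrs[(m, g)].append(est.hr)
                if est.p_value < spec.alpha:
                    rejections[(m, g)] += 1
        if progress_every and (r + 1) % progress_every == 0:
            logger.info("replication %d/%d done", r + 1, spec.n_replications)

    cells = {}
    for (m, g), values in hrs.items():
        true = spec.true_hr.get(g, 1.0)
        arr = np.asarray(values, dtype=float)
        n_est = len(arr)
        if n_est == 0:
            logger.warning(
                "method %s, group %s: never estimable in %d replications",
                m,
                g,
                spec.n_replications,
            )
            mean_hr = bias = mse = float("nan")
        else:
            mean_hr = float(arr.mean())
            bias = mean_hr - true
            mse = float(np.mean((arr - true) ** 2))
        cells[(m, g)] = CellResult(
            method=m,
            group=g,
            n_replications=spec.n_replications,
            n_estimable=n_est,
            rejection_count=rejections[(m, g)],
            mean_hr=mean_hr,
            bias=bias,
            mse=mse,
        )
        excluded = spec.n_replications - n_est
        if excluded:
            logger.info(
                "method %s, group %s: %d replication(s) non-estimable, excluded",
                m,
                g,
                excluded,
            )
    logger.info("scenario end (%d non-converged fits)", n_not_converged)
    return ScenarioResult(spec=spec, cells=cells, n_not_converged=n_not_converged)


def tabulate(
    results: Sequence[ScenarioResult], layout: str
) -> pd.DataFrame:
    """Arrange scenario results as a publication-style table.

    ``layout='type1'`` and ``layout='power'`` give rejection counts with one
    column per method (including each landmark time); ``layout='bias_mse'``
    gives a bias and an MSE column per method.  Rows are (beta0 label, dose
    group).
    """
    if layout not in ("type1", "power", "bias_mse"):
        raise ValueError(f"unknown layout: {layout!r}")
    if not results:
        raise DataError("no scenario results to tabulate")
    method_keys = results[0].spec.method_keys
    group_sets = {
        tuple(sorted({g for (_, g) in res.cells})) for res in results
    }
    if len(group_sets) != 1 or any(
        res.spec.method_keys != method_keys for res in results
    ):
        raise DataError(
            "scenario results have inconsistent method/group sets"
        )
    present = {g for (_, g) in results[0].cells}
    groups = [g for g in (*GROUP_LABELS, "user") if g in present]

    rows = []
    for res in results:
        label = beta0_label(res.spec.config.beta0)
        for g in groups:
            row = {"beta0": label, "dose_group": g}
            for m in method_keys:
                cell = res.cells.get((m, g))
                if layout in ("type1", "power"):
                    row[m] = cell.rejection_count if cell else pd.NA
                else:
                    row[f"{m}_bias"] = cell.bias if cell else float("nan")
                    row[f"{m}_mse"] = cell.mse if cell else float("nan")
            rows.append(row)
    return pd.DataFrame(rows)


def plot_rejection_rates(result: ScenarioResult, path=None):
    """Bar chart of per-method rejection rates by dose group.

    A minimal diagnostic helper; returns the matplotlib figure.  Saves to
    ``path`` if given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    method_keys = result.spec.method_keys
    groups = sorted({g for (_, g) in result.cells})
    fig, ax = plt.subplots(figsize=(7, 4))
    width = 0.8 / len(method_keys)
    x = np.arange(len(groups))
    for i, m in enumerate(method_keys):
        rates = [
            result.cells[(m, g)].rejection_rate if (m, g) in result.cells else np.nan
            for g in groups
        ]
        ax.bar(x + i * width, rates, width=width, label=m)
    ax.axhline(result.spec.alpha, color="k", ls="--", lw=0.8)
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels(groups)
    ax.set_ylabel("rejection rate")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
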