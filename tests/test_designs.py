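"""Tests for the naive, counting-process and landmark design builders."""

import numpy as np
import pandas as pd
import pytest

from gtbias import (
    SimulationConfig,
    fit_cox,
    make_counting_process,
    make_landmark_design,
    make_naive_design,
    simulate_cohort,
)
from gtbias.exceptions import DataError


def subjects_frame(rows):
    df = pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "intended_user",
            "initiation_interval",
            "followup_end",
            "event",
            "final_dose_category",
        ],
    )
    df["initiation_interval"] = df["initiation_interval"].astype("Int64")
    return df


def long_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["subject_id", "interval", "z1", "z2", "z3", "event_this_interval"],
    )


def expand_user_long(sid, w, end, event, dose=0.5, cuts=(1.5, 3.0)):
    """Per-interval rows for one user; independent of the simulator path."""
    rows = []
    for t in range(1, end + 1):
        cum = dose * (t - w + 1) if t >= w else 0.0
        code = (cum > 0) + (cum > cuts[0]) + (cum > cuts[1])
        rows.append(
            (sid, t, int(code == 1), int(code == 2), int(code == 3),
             event and t == end)
        )
    return rows


class TestNaiveDesign:
    def test_non_user_with_event(self):
        subjects = subjects_frame([(1, False, pd.NA, 2, True, "none")])
        design = make_naive_design(subjects)
        row = design.iloc[0]
        assert row["time"] == 2 and row["event"]
        assert (row[["z1", "z2", "z3"]] == 0).all()

    def test_full_exposure_coded_high_from_time_zero(self):
        # W=1, censored at 10, cumulative dose 5.0 -> high under (1.5, 3.0)
        subjects = subjects_frame([(1, True, 1, 10, False, "high")])
        design = make_naive_design(subjects)
        row = design.iloc[0]
        assert row["time"] == 10 and not row["event"]
        assert (row["z1"], row["z2"], row["z3"]) == (0, 0, 1)

    def test_empty_cohort_rejected(self):
        with pytest.raises(DataError):
            make_naive_design(subjects_frame([]))

    def test_all_non_user_cohort_flags_groups_downstream(self):
        subjects = subjects_frame(
            [(i, False, pd.NA, 10 if i > 2 else i, i <= 2, "none")
             for i in range(1, 8)]
        )
        result = fit_cox(make_naive_design(subjects))
        assert result.estimates == {}
        assert set(result.non_estimable) == {"low", "moderate", "high"}


class TestCountingProcess:
    def test_single_unexposed_spell(self):
        long = long_frame([(1, 1, 0, 0, 0, False), (1, 2, 0, 0, 0, False),
                           (1, 3, 0, 0, 0, True)])
        cp = make_counting_process(long)
        assert len(cp) == 1
        row = cp.iloc[0]
        assert (row["start"], row["stop"]) == (0.0, 3.0)
        assert row["event"]

    def test_category_switches_at_dose_crossings(self):
        # W=4, dose 0.5, cutpoints (1.5, 3.0), censored at 10: the cumulative
        # dose 0.5*(t-3) crosses into moderate at t=7 and into high at t=10
        long = long_frame(expand_user_long(1, w=4, end=10, event=False))
        cp = make_counting_process(long).reset_index(drop=True)
        spells = list(
            zip(cp["start"], cp["stop"], cp["z1"], cp["z2"], cp["z3"])
        )
        assert spells == [
            (0.0, 3.0, 0, 0, 0),
            (3.0, 6.0, 1, 0, 0),
            (6.0, 9.0, 0, 1, 0),
            (9.0, 10.0, 0, 0, 1),
        ]
        assert not cp["event"].any()

    def test_person_time_conserved(self, small_cohort):
        _, subjects, long = small_cohort
        cp = make_counting_process(long)
        person_time = (cp["stop"] - cp["start"]).groupby(cp["subject_id"]).sum()
        expected = subjects.set_index("subject_id")["followup_end"]
        assert np.allclose(person_time.sort_index(), expected.sort_index())

    def test_overlapping_intervals_rejected(self):
        long = long_frame([(1, 1, 0, 0, 0, False), (1, 1, 0, 0, 0, False)])
        with pytest.raises(DataError):
            make_counting_process(long)

    def test_gap_rejected(self):
        long = long_frame([(1, 1, 0, 0, 0, False), (1, 3, 0, 0, 0, True)])
        with pytest.raises(DataError):
            make_counting_process(long)

    def test_merged_and_unmerged_rows_give_identical_fit(self):
        config = SimulationConfig(n_subjects=600, seed=31)
        _, long = simulate_cohort(config)
        merged = make_counting_process(long)
        unmerged = pd.DataFrame(
            {
                "subject_id": long["subject_id"],
                "start": long["interval"] - 1.0,
                "stop": long["interval"].astype(float),
                "z1": long["z1"],
                "z2": long["z2"],
                "z3": long["z3"],
                "event": long["event_this_interval"],
            }
        )
        fit_m = fit_cox(merged)
        fit_u = fit_cox(unmerged)
        assert set(fit_m.estimates) == set(fit_u.estimates)
        for g in fit_m.estimates:
            assert fit_m.estimates[g].log_hr == pytest.approx(
                fit_u.estimates[g].log_hr, abs=1e-8
            )
            assert fit_m.estimates[g].se == pytest.approx(
                fit_u.estimates[g].se, abs=1e-8
            )


class TestLandmarkDesign:
    def make_pair(self, spec_rows):
        """spec_rows: (sid, w or None, end, event)."""
        srows, lrows = [], []
        for sid, w, end, event in spec_rows:
            cum_end = 0.5 * (end - w + 1) if w is not None and end >= w else 0.0
            code = (cum_end > 0) + (cum_end > 1.5) + (cum_end > 3.0)
            label = ["none", "low", "moderate", "high"][code]
            srows.append((sid, w is not None, w if w is not None else pd.NA,
                          end, event, label))
            if w is None:
                lrows += [(sid, t, 0, 0, 0, event and t == end)
                          for t in range(1, end + 1)]
            else:
                lrows += expand_user_long(sid, w, end, event)
        return subjects_frame(srows), long_frame(lrows)

    def test_pre_landmark_events_excluded(self):
        subjects, long = self.make_pair(
            [(1, None, 4, True), (2, None, 10, False), (3, None, 5, True)]
        )
        design = make_landmark_design(subjects, long, tau=5, n_intervals=10)
        assert set(design["subject_id"]) == {2}

    def test_initiation_after_landmark_is_unexposed(self):
        subjects, long = self.make_pair([(1, 7, 10, False), (2, None, 10, False)])
        design = make_landmark_design(subjects, long, tau=5, n_intervals=10)
        assert (design[["z1", "z2", "z3"]].to_numpy() == 0).all()

    def test_exposure_frozen_at_landmark_dose(self):
        # W=2, dose 0.5: cumulative dose at tau=5 is 2.0 -> moderate,
        # even though the subject later reaches high
        subjects, long = self.make_pair([(1, 2, 10, False), (2, None, 10, False)])
        design = make_landmark_design(subjects, long, tau=5, n_intervals=10)
        row = design[design["subject_id"] == 1].iloc[0]
        assert (row["z1"], row["z2"], row["z3"]) == (0, 1, 0)
        assert row["time"] == 5.0  # clock restarts at the landmark

    def test_binary_coding_collapses_to_user_indicator(self):
        subjects, long = self.make_pair(
            [(1, 2, 10, False), (2, 7, 10, False), (3, None, 10, True)]
        )
        design = make_landmark_design(
            subjects, long, tau=5, n_intervals=10, coding="binary"
        )
        users = design.set_index("subject_id")["user"]
        assert users[1] == 1 and users[2] == 0 and users[3] == 0

    def test_tau_outside_horizon_rejected(self):
        subjects, long = self.make_pair([(1, None, 10, False)])
        for tau in (0, 10, 11):
            with pytest.raises(ValueError):
                make_landmark_design(subjects, long, tau=tau, n_intervals=10)

    def test_no_survivors_is_data_error(self):
        subjects, long = self.make_pair([(1, None, 3, True), (2, None, 2, True)])
        with pytest.raises(DataError):
            make_landmark_design(subjects, long, tau=5, n_intervals=10)

    def test_never_contains_subject_censored_at_landmark(self, small_cohort):
        _, subjects, long = small_cohort
        for tau in (3, 5, 7):
            design = make_landmark_design(subjects, long, tau=tau, n_intervals=10)
            kept = subjects.set_index("subject_id").loc[design["subject_id"]]
            assert (kept["followup_end"] > tau).all()
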