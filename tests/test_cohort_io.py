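"""Cohort tables: loading, validation, survival times, exclusions."""

import numpy as np
import pandas as pd
import pytest

from jlcmm import (apply_visit_exclusions, compute_survival_time,
                   default_scenario, exclude_prior_depression,
                   generate_cohort, read_cohort, recenter_time, write_cohort)
from jlcmm.cohort import CohortData, CohortSchema


def _toy_tables():
    visits = pd.DataFrame({
        "subject_id": ["a", "a", "a", "b", "b"],
        "t": [-2.0, 1.0, 3.0, -1.0, 0.5],
        "y": [1, 2, 3, 5, 4],
    })
    subjects = pd.DataFrame({
        "subject_id": ["a", "b"],
        "T": [4.0, 2.0],
        "delta": [0, 1],
        "age_at_baseline": [81.0, 79.5],
        "history_depression": [False, True],
    })
    return visits, subjects


class TestReadWrite:
    def test_toy_pair_loads_with_counts_preserved(self, tmp_path):
        visits, subjects = _toy_tables()
        visits.to_csv(tmp_path / "v.csv", index=False)
        subjects.to_csv(tmp_path / "s.csv", index=False)
        cohort = read_cohort(tmp_path / "v.csv", tmp_path / "s.csv")
        assert cohort.n_subjects == 2
        assert len(cohort.visits) == 5

    def test_score_out_of_bounds_rejected(self, tmp_path):
        visits, subjects = _toy_tables()
        visits.loc[0, "y"] = 16
        visits.to_csv(tmp_path / "v.csv", index=False)
        subjects.to_csv(tmp_path / "s.csv", index=False)
        with pytest.raises(ValueError, match=r"\[0, 15\]"):
            read_cohort(tmp_path / "v.csv", tmp_path / "s.csv")

    def test_missing_mandatory_column_rejected(self, tmp_path):
        visits, subjects = _toy_tables()
        visits.drop(columns="y").to_csv(tmp_path / "v.csv", index=False)
        subjects.to_csv(tmp_path / "s.csv", index=False)
        with pytest.raises(ValueError, match="missing column 'y'"):
            read_cohort(tmp_path / "v.csv", tmp_path / "s.csv")

    def test_missing_scores_dropped_with_count(self, tmp_path, caplog):
        visits, subjects = _toy_tables()
        visits.loc[1, "y"] = np.nan
        visits.to_csv(tmp_path / "v.csv", index=False)
        subjects.to_csv(tmp_path / "s.csv", index=False)
        with caplog.at_level("INFO", logger="jlcmm.cohort"):
            cohort = read_cohort(tmp_path / "v.csv", tmp_path / "s.csv")
        assert len(cohort.visits) == 4
        assert "1 visit rows" in caplog.text

    def test_synthetic_cohort_round_trips(self, tmp_path):
        sc = default_scenario()
        sc.n_subjects = 40
        cohort, _ = generate_cohort(sc, seed=4)
        write_cohort(cohort, tmp_path / "v.csv", tmp_path / "s.csv")
        back = read_cohort(tmp_path / "v.csv", tmp_path / "s.csv")
        pd.testing.assert_frame_equal(back.visits, cohort.visits,
                                      check_dtype=False)
        pd.testing.assert_frame_equal(back.subjects, cohort.subjects,
                                      check_dtype=False)


class TestVisitExclusions:
    def test_censored_subject_keeps_all_visits(self):
        visits, subjects = _toy_tables()
        out = apply_visit_exclusions(CohortData(visits, subjects))
        assert (out.visits["subject_id"] == "a").sum() == 3

    def test_post_dementia_visit_removed_boundary_retained(self):
        visits = pd.DataFrame({"subject_id": ["b"] * 3,
                               "t": [-1.0, 2.0, 3.0], "y": [1, 1, 1]})
        subjects = pd.DataFrame({"subject_id": ["b"], "T": [2.0],
                                 "delta": [1]})
        out = apply_visit_exclusions(CohortData(visits, subjects))
        # visit at exactly the diagnosis time stays; later visit goes
        assert sorted(out.visits["t"]) == [-1.0, 2.0]

    def test_idempotent(self):
        visits, subjects = _toy_tables()
        once = apply_visit_exclusions(CohortData(visits, subjects))
        twice = apply_visit_exclusions(once)
        pd.testing.assert_frame_equal(once.visits, twice.visits)

    def test_generated_cohorts_have_no_post_dementia_visits(self):
        sc = default_scenario()
        sc.n_subjects = 300
        cohort, _ = generate_cohort(sc, seed=9)
        out = apply_visit_exclusions(cohort)
        assert len(out.visits) == len(cohort.visits)


class TestSurvivalTime:
    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            (dict(dementia_time=4.0, death_time=6.0, last_assessment=7.0,
                  admin_end=13.0), (4.0, 1)),
            (dict(death_time=6.0, admin_end=13.0), (6.0, 2)),
            (dict(last_assessment=9.5, admin_end=13.0), (9.5, 0)),
            (dict(dementia_time=5.0, death_time=5.0), (5.0, 1)),  # tie
            (dict(dementia_time=8.0, last_assessment=6.0, admin_end=13.0),
             (6.0, 0)),
        ],
    )
    def test_first_event_rule(self, kwargs, expected):
        assert compute_survival_time(**kwargs) == expected

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError, match="no event"):
            compute_survival_time()

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError, match="nonpositive"):
            compute_survival_time(dementia_time=-1.0)

    def test_dementia_flag_requires_dementia_minimum(self):
        # death earlier than dementia: never coded as dementia
        T, delta = compute_survival_time(dementia_time=5.0, death_time=3.0)
        assert (T, delta) == (3.0, 2)


class TestRecenter:
    def test_baseline_mode_is_identity(self):
        visits, subjects = _toy_tables()
        cohort = CohortData(visits, subjects)
        assert recenter_time(cohort, "baseline-centered") is cohort

    def test_age_centering_arithmetic(self):
        visits = pd.DataFrame({"subject_id": ["a"], "t": [0.0], "y": [1]})
        subjects = pd.DataFrame({"subject_id": ["a"], "T": [5.0],
                                 "delta": [0], "age_at_baseline": [72.0]})
        out = recenter_time(CohortData(visits, subjects), "age-centered",
                            center=80.0)
        assert out.visits["t"].iloc[0] == pytest.approx(-8.0)
        # survival stays on the study clock
        assert out.subjects["T"].iloc[0] == 5.0

    def test_round_trip_restores_original_times(self):
        visits, subjects = _toy_tables()
        cohort = CohortData(visits, subjects)
        out = recenter_time(cohort, "age-centered", center=80.0)
        np.testing.assert_allclose(out.visits["t_baseline"],
                                   cohort.visits["t"])
        age = out.subjects.set_index("subject_id")["age_at_baseline"]
        back = out.visits["t"] - out.visits["subject_id"].map(age) + 80.0
        np.testing.assert_allclose(back, cohort.visits["t"])

    def test_missing_age_rejected(self):
        visits, subjects = _toy_tables()
        subjects = subjects.drop(columns="age_at_baseline")
        with pytest.raises(ValueError, match="age_at_baseline"):
            recenter_time(CohortData(visits, subjects), "age-centered")


class TestPriorDepressionExclusion:
    def test_unflagged_cohort_unchanged(self):
        visits, subjects = _toy_tables()
        subjects["history_depression"] = False
        out = exclude_prior_depression(CohortData(visits, subjects))
        assert out.n_subjects == 2

    def test_flagged_subjects_and_their_visits_removed(self):
        visits, subjects = _toy_tables()
        out = exclude_prior_depression(CohortData(visits, subjects))
        assert out.n_subjects == 1
        assert set(out.visits["subject_id"]) == {"a"}

    def test_removed_count_matches_generator_prevalence_draw(self):
        sc = default_scenario()
        sc.n_subjects = 400
        cohort, truth = generate_cohort(sc, seed=21)
        flagged = int(cohort.subjects["history_depression"].sum())
        out = exclude_prior_depression(cohort)
        assert out.n_subjects == 400 - flagged


def test_orphan_visits_rejected():
    visits, subjects = _toy_tables()
    visits.loc[0, "subject_id"] = "zzz"
    with pytest.raises(ValueError, match="unknown subjects"):
        CohortData(visits, subjects)
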