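"""Cohort tables, survival-time construction and exclusion rules.

Two plain CSV tables describe a cohort:

* **visits** — one row per depressive-symptom assessment:
  ``subject_id, t, y`` plus covariate columns.  ``t`` is in decimal years
  relative to the centering baseline (negative during the earlier study
  period), ``y`` is the integer GDS-15 score (0-15).
* **subjects** — one row per woman: ``subject_id, T, delta,
  age_at_baseline, history_depression, wm_svid, adps`` plus covariates.
  ``T`` is the event/censoring time in years from the centering baseline,
  ``delta`` codes the outcome (0 censored, 1 dementia, 2 death),
  ``age_at_baseline`` is the age in years at the centering time,
  ``wm_svid``/``adps`` are the optional MRI measures (missing outside the
  imaging subsample).

Times are reals, not dates; :func:`years_between` converts ISO dates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import date

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CohortSchema",
    "CohortData",
    "read_cohort",
    "write_cohort",
    "apply_visit_exclusions",
    "compute_survival_time",
    "recenter_time",
    "exclude_prior_depression",
    "years_between",
]

VISIT_REQUIRED = ("subject_id", "t", "y")
SUBJECT_REQUIRED = ("subject_id", "T", "delta")

DAYS_PER_YEAR = 365.25


def years_between(d: date, baseline: date) -> float:
    """Decimal years from ``baseline`` to ``d`` (negative if earlier)."""
    return (d - baseline).days / DAYS_PER_YEAR


@dataclass
class CohortSchema:
    """Which covariate columns feed which model component.

    ``categorical`` maps a column name to its ordered levels (first level =
    reference); such columns are dummy-expanded when model matrices are
    built.  Missing values in a categorical column become an explicit
    ``"missing"`` level; rows missing a *continuous* covariate are excluded
    (with a logged count) from stages that need that column.
    """

    long_covariates: list = field(default_factory=list)
    surv_covariates: list = field(default_factory=list)
    categorical: dict = field(default_factory=dict)


@dataclass
class CohortData:
    visits: pd.DataFrame
    subjects: pd.DataFrame
    schema: CohortSchema = field(default_factory=CohortSchema)

    def __post_init__(self):
        self.validate()

    def validate(self):
        for col in VISIT_REQUIRED:
            if col not in self.visits.columns:
                raise ValueError(f"visits table missing column '{col}'")
        for col in SUBJECT_REQUIRED:
            if col not in self.subjects.columns:
                raise ValueError(f"subjects table missing column '{col}'")
        y = self.visits["y"]
        bad = self.visits.index[(y < 0) | (y > 15) | ~np.isfinite(y)]
        if len(bad):
            raise ValueError(
                f"GDS-15 score outside [0, 15] at visit rows {list(bad[:5])}"
            )
        if not np.all(np.isfinite(self.visits["t"])):
            raise ValueError("non-finite visit times")
        T = self.subjects["T"].to_numpy(dtype=float)
        if np.any(~np.isfinite(T)) or np.any(T <= 0):
            raise ValueError("survival times must be positive and finite")
        d = self.subjects["delta"]
        if not d.isin([0, 1, 2]).all():
            raise ValueError("delta must be 0 (censored), 1 (dementia) or 2 (death)")
        if self.subjects["subject_id"].duplicated().any():
            raise ValueError("duplicate subject_id in subjects table")
        known = set(self.subjects["subject_id"])
        orphans = set(self.visits["subject_id"]) - known
        if orphans:
            raise ValueError(
                f"visits reference unknown subjects: {sorted(orphans)[:5]}"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def copy(self) -> "CohortData":
        return CohortData(self.visits.copy(), self.subjects.copy(),
                          replace(self.schema))


def read_cohort(visits_path, subjects_path,
                schema: CohortSchema | None = None) -> CohortData:
    """Load and validate a cohort from its two CSV files.

    Visit rows with a missing score are dropped (count logged); score
    bounds, delta codes and referential integrity are enforced.
    """
    visits = pd.read_csv(visits_path)
    subjects = pd.read_csv(subjects_path)
    n_miss = int(visits["y"].isna().sum()) if "y" in visits else 0
    if n_miss:
        logger.info("dropping %d visit rows with missing score", n_miss)
        visits = visits.dropna(subset=["y"]).reset_index(drop=True)
    if "history_depression" in subjects:
        subjects["history_depression"] = subjects[
            "history_depression"
        ].astype(bool)
    return CohortData(visits, subjects, schema or CohortSchema())


def write_cohort(cohort: CohortData, visits_path, subjects_path) -> None:
    """Write the two cohort tables as CSV (floats at full precision)."""
    cohort.visits.to_csv(visits_path, index=False)
    cohort.subjects.to_csv(subjects_path, index=False)


def apply_visit_exclusions(cohort: CohortData) -> CohortData:
    """Drop symptom assessments made after a dementia diagnosis.

    Only subjects with ``delta = 1`` are affected; visits at exactly the
    diagnosis time are retained (the rule is strictly "after").  Idempotent.
    """
    dem = cohort.subjects.loc[cohort.subjects["delta"] == 1,
                              ["subject_id", "T"]]
    dem_time = dict(zip(dem["subject_id"], dem["T"]))
    limit = cohort.visits["subject_id"].map(dem_time)
    keep = limit.isna() | (cohort.visits["t"] <= limit)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("excluding %d post-dementia assessments", n_drop)
    return CohortData(cohort.visits[keep].reset_index(drop=True),
                      cohort.subjects.copy(), cohort.schema)


def compute_survival_time(dementia_time=None, death_time=None,
                          last_assessment=None, admin_end=None):
    """First of dementia, death, last assessment or administrative end.

    Returns ``(T, delta)``: delta 1 if dementia is (weakly) earliest, 2 if
    death precedes any dementia, else 0.  A dementia/death tie resolves to
    dementia, the event of interest.
    """
    candidates = {}
    if dementia_time is not None:
        candidates[1] = float(dementia_time)
    if death_time is not None:
        candidates[2] = float(death_time)
    for code, t in ((0, last_assessment), (0, admin_end)):
        if t is not None:
            candidates[code] = min(candidates.get(code, np.inf), float(t))
    if not candidates:
        raise ValueError("no event, assessment or administrative time given")
    T = min(candidates.values())
    if T <= 0:
        raise ValueError(f"nonpositive survival time {T}")
    if candidates.get(1) == T:
        return T, 1
    if candidates.get(2) == T:
        return T, 2
    return T, 0


def recenter_time(cohort: CohortData, mode: str = "baseline-centered",
                  center: float = 80.0) -> CohortData:
    """Switch the longitudinal time scale.

    ``baseline-centered`` returns the cohort unchanged (years from the
    late-study baseline).  ``age-centered`` replaces each visit time by age
    at the visit minus ``center`` (age 80 in the sensitivity analysis);
    original times are kept in a ``t_baseline`` column.  Event times stay on
    the study clock — only the mixed-model time scale changes.
    """
    if mode == "baseline-centered":
        return cohort
    if mode != "age-centered":
        raise ValueError(f"unknown recentering mode '{mode}'")
    if "age_at_baseline" not in cohort.subjects:
        raise ValueError("age-centered mode needs age_at_baseline")
    age = cohort.subjects.set_index("subject_id")["age_at_baseline"]
    if age.isna().any():
        raise ValueError("missing age_at_baseline for some subjects")
    visits = cohort.visits.copy()
    base_age = visits["subject_id"].map(age)
    visits["t_baseline"] = visits["t"]
    visits["t"] = base_age + visits["t"] - center
    return CohortData(visits, cohort.subjects.copy(), cohort.schema)


def exclude_prior_depression(cohort: CohortData) -> CohortData:
    """Remove subjects with a self-reported history of depression."""
    if "history_depression" not in cohort.subjects:
        raise ValueError("subjects table lacks history_depression")
    flagged = cohort.subjects["history_depression"].astype(bool)
    n = int(flagged.sum())
    if n:
        logger.info("excluding %d subjects with prior depression", n)
    keep_ids = set(cohort.subjects.loc[~flagged, "subject_id"])
    return CohortData(
        cohort.visits[cohort.visits["subject_id"].isin(keep_ids)]
        .reset_index(drop=True),
        cohort.subjects[~flagged].reset_index(drop=True),
        cohort.schema,
    )
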