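"""Synthetic cohort generator with known ground truth.

The real cohort (annual GDS-15 assessments across two study periods,
competing dementia/death outcomes, an MRI subsample) is application-
restricted, so every downstream stage is exercised on simulated cohorts
that emulate its published structure: five latent classes with the printed
mixing proportions, class-specific piecewise-linear symptom trajectories
(kink at the late-study baseline, t = 0), an annual visit grid spanning
t = -9..9 with 5-19 attended assessments per woman (mean 14.4),
class-specific Weibull dementia hazards matching the printed hazard ratios,
competing non-dementia mortality, administrative censoring at t = 13, and
class-conditional MRI measures (log-normal WM-SVID, logit-normal AD-PS)
drawn for a 569/957 subsample.

Trajectories are specified on the observable 0-15 score scale and
discretised by rounding and clipping; the resulting floor effect is exactly
the skewness the fitted model's monotone spline link is there to absorb.
"""

from __future__ import annotations

import io
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from .cohort import CohortData, CohortSchema

__all__ = [
    "ScenarioConfig",
    "default_scenario",
    "generate_cohort",
    "summarize_cohort",
    "generate_class_exposure_sample",
]

CLASS_NAMES = (
    "minimal_stable",
    "mild_stable",
    "remitting_relapsing",
    "emerging_mid",
    "emerging_late",
)


@dataclass
class ScenarioConfig:
    """Complete generator truth for one simulated cohort."""

    n_subjects: int = 957
    class_names: list = field(default_factory=lambda: list(CLASS_NAMES))
    pi: list = field(default_factory=lambda: [0.36, 0.25, 0.05, 0.09, 0.25])
    # trajectory truth on the GDS scale: level at t = 0, slope before,
    # slope after (per year)
    intercept: list = field(
        default_factory=lambda: [0.50, 2.70, 2.30, 3.24, 0.60])
    slope_pre: list = field(
        default_factory=lambda: [0.0, 0.0, -0.25, 0.30, 0.0])
    slope_post: list = field(
        default_factory=lambda: [0.0, 0.0, 0.25, 0.44, 0.30])
    sigma_b: float = 0.8
    sigma_e: float = 1.0
    # cause-specific Weibull baselines (dementia, death); scales calibrated
    # so the reference class reaches ~11% dementia incidence and ~33%
    # competing mortality by the administrative end
    weibull_shape: list = field(default_factory=lambda: [2.0, 1.5])
    weibull_scale: list = field(default_factory=lambda: [33.61, 22.81])
    log_hr_dementia: list = field(
        default_factory=lambda: [float(np.log(h))
                                 for h in (1.0, 1.82, 2.11, 5.10, 2.78)])
    log_hr_death: list = field(default_factory=lambda: [0.0] * 5)
    # visit process: annual grid over [t_first, t_last], random start delay,
    # at-random attendance, loss to follow-up, administrative end
    t_first: int = -9
    t_last: int = 9
    start_delay_probs: list = field(
        default_factory=lambda: [0.55, 0.20, 0.12, 0.08, 0.05])
    attend_prob: float = 0.875
    dropout_prob: float = 0.12
    admin_end: float = 13.0
    min_visits: int = 5
    # baseline covariates (age at the earlier-study baseline, by class)
    age_mean: list = field(
        default_factory=lambda: [72.03, 73.18, 71.75, 73.54, 73.06])
    age_sd: list = field(
        default_factory=lambda: [3.19, 3.66, 3.16, 3.66, 3.51])
    history_depression_prev: list = field(
        default_factory=lambda: [13 / 343, 43 / 237, 5 / 44, 3 / 90,
                                 10 / 243])
    # MRI truth: target mean/SD of each class-conditional distribution
    mri_fraction: float = 569 / 957
    wm_svid_mean: list = field(
        default_factory=lambda: [2.56, 4.17, 2.13, 5.17, 2.87])
    wm_svid_sd: list = field(
        default_factory=lambda: [3.64, 5.19, 2.92, 6.90, 3.33])
    adps_mean: list = field(
        default_factory=lambda: [0.23, 0.31, 0.27, 0.31, 0.33])
    adps_sd: list = field(
        default_factory=lambda: [0.16, 0.19, 0.17, 0.17, 0.22])
    seed: int = 0

    @property
    def G(self) -> int:
        return len(self.pi)

    def validate(self):
        pi = np.asarray(self.pi)
        if np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-8:
            raise ValueError("class proportions must be positive, sum to 1")
        if self.sigma_b < 0 or self.sigma_e < 0:
            raise ValueError("noise SDs must be nonnegative")
        if not 0 < self.attend_prob <= 1:
            raise ValueError("attend_prob must be in (0, 1]")
        n_slots = self.t_last - self.t_first + 1 - (len(
            self.start_delay_probs) - 1)
        if n_slots < self.min_visits:
            raise ValueError(
                "visit schedule infeasible: latest start leaves fewer slots "
                "than min_visits")

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ScenarioConfig":
        if isinstance(source, (str, io.IOBase)) and "\n" in str(source):
            d = yaml.safe_load(source)
        else:
            with open(source) as fh:
                d = yaml.safe_load(fh)
        return cls(**d)


def default_scenario() -> ScenarioConfig:
    """The published-cohort-calibrated scenario (five classes)."""
    sc = ScenarioConfig()
    sc.validate()
    return sc


# ---------------------------------------------------------------------------
# moment matching for the MRI distributions


def _lognormal_params(mean, sd):
    """(mu, sigma) of a log-normal with given mean and SD."""
    v = sd**2
    sigma2 = np.log(1.0 + v / mean**2)
    return np.log(mean) - 0.5 * sigma2, np.sqrt(sigma2)


_GH_X, _GH_W = np.polynomial.hermite_e.hermegauss(80)
_GH_W = _GH_W / _GH_W.sum()


def _logitnormal_moments(mu, s):
    z = expit(mu + s * _GH_X)
    m = float(_GH_W @ z)
    v = float(_GH_W @ (z - m) ** 2)
    return m, np.sqrt(v)


def _logitnormal_params(mean, sd):
    """(mu, s) of a logit-normal matching a target mean and SD."""
    def sd_given_mu_for(s):
        # for fixed s, solve mu for the mean, then report the sd gap
        mu = brentq(lambda m: _logitnormal_moments(m, s)[0] - mean, -20, 20)
        return mu, _logitnormal_moments(mu, s)[1] - sd

    s = brentq(lambda v: sd_given_mu_for(v)[1], 1e-3, 8.0)
    mu = sd_given_mu_for(s)[0]
    return mu, s


# ---------------------------------------------------------------------------
# generation


def generate_cohort(scenario: ScenarioConfig, seed: int | None = None):
    """Simulate one cohort; returns ``(CohortData, truth)``.

    ``truth`` is a per-subject DataFrame with the latent class, random
    intercept and pre-censoring event times — the oracle against which
    recovery is judged.  A fixed seed yields a bit-identical cohort (one
    ``numpy`` Generator stream drawn in a fixed order).
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    n = scenario.n_subjects
    G = scenario.G
    pi = np.asarray(scenario.pi)
    cls = rng.choice(G, size=n, p=pi)
    b = rng.normal(0.0, scenario.sigma_b, n)

    shapes = np.asarray(scenario.weibull_shape)
    scales = np.asarray(scenario.weibull_scale)
    log_hr = np.column_stack([scenario.log_hr_dementia,
                              scenario.log_hr_death])
    u = rng.uniform(size=(n, 2))
    lat = np.empty((n, 2))
    for k in range(2):
        lp = log_hr[cls, k]
        lat[:, k] = scales[k] * (-np.log(u[:, k]) / np.exp(lp)) ** (
            1.0 / shapes[k])
    drop = np.where(rng.uniform(size=n) < scenario.dropout_prob,
                    rng.uniform(0.5, scenario.admin_end, n), np.inf)
    censor = np.minimum(scenario.admin_end, drop)
    T = np.minimum(np.minimum(lat[:, 0], lat[:, 1]), censor)
    delta = np.zeros(n, dtype=int)
    delta[np.isclose(T, lat[:, 0])] = 1  # dementia wins ties
    delta[(delta == 0) & np.isclose(T, lat[:, 1])] = 2

    delays = rng.choice(len(scenario.start_delay_probs), size=n,
                        p=scenario.start_delay_probs)
    age_whisca = rng.normal(np.asarray(scenario.age_mean)[cls],
                            np.asarray(scenario.age_sd)[cls])
    hist_dep = rng.uniform(size=n) < np.asarray(
        scenario.history_depression_prev)[cls]
    in_mri = rng.uniform(size=n) < scenario.mri_fraction

    icpt = np.asarray(scenario.intercept)
    s_pre = np.asarray(scenario.slope_pre)
    s_post = np.asarray(scenario.slope_post)

    visit_rows = []
    for i in range(n):
        start = scenario.t_first + delays[i]
        grid = np.arange(start, scenario.t_last + 1, dtype=float)
        # eligibility: alive and under follow-up; post-dementia assessments
        # never happen (generation matches the analysis exclusion rule)
        if delta[i] == 1:
            grid = grid[grid <= T[i]]
        else:
            grid = grid[grid < T[i]]
        att = rng.uniform(size=grid.size) < scenario.attend_prob
        if att.sum() < scenario.min_visits:
            # the cohort definition requires a minimal assessment history;
            # restore the earliest missed slots
            missed = np.where(~att)[0]
            need = min(scenario.min_visits - int(att.sum()), missed.size)
            att[missed[:need]] = True
        t_i = grid[att]
        g = cls[i]
        mean = (icpt[g] + s_pre[g] * np.minimum(t_i, 0.0)
                + s_post[g] * np.maximum(t_i, 0.0))
        y = np.clip(np.round(mean + b[i]
                             + rng.normal(0.0, scenario.sigma_e, t_i.size)),
                    0, 15).astype(int)
        visit_rows.append(pd.DataFrame(
            {"subject_id": i, "t": t_i, "y": y}))

    # MRI measures, class-conditional
    wm = np.full(n, np.nan)
    adps = np.full(n, np.nan)
    for g in range(G):
        sel = (cls == g) & in_mri
        m = int(sel.sum())
        if not m:
            continue
        mu, s = _lognormal_params(scenario.wm_svid_mean[g],
                                  scenario.wm_svid_sd[g])
        wm[sel] = rng.lognormal(mu, s, m)
        mu, s = _logitnormal_params(scenario.adps_mean[g],
                                    scenario.adps_sd[g])
        adps[sel] = np.clip(expit(rng.normal(mu, s, m)), 0.0, 1.0)

    subjects = pd.DataFrame({
        "subject_id": np.arange(n),
        "T": T,
        "delta": delta,
        "age_at_baseline": age_whisca + 9.0,  # age at the centering time
        "age_whisca": age_whisca,
        "history_depression": hist_dep,
        "wm_svid": wm,
        "adps": adps,
    })
    visits = pd.concat(visit_rows, ignore_index=True)
    truth = pd.DataFrame({
        "subject_id": np.arange(n),
        "true_class": cls,
        "random_intercept": b,
        "latent_dementia_time": lat[:, 0],
        "latent_death_time": lat[:, 1],
        "censor_time": censor,
    })
    cohort = CohortData(visits, subjects, CohortSchema())
    return cohort, truth


def summarize_cohort(cohort: CohortData, truth: pd.DataFrame | None = None
                     ) -> dict:
    """Descriptive summary: assessment schedule, events, MRI subsample."""
    if cohort.n_subjects == 0:
        raise ValueError("empty cohort")
    counts = cohort.visits.groupby("subject_id").size()
    counts = counts.reindex(cohort.subjects["subject_id"], fill_value=0)
    delta = cohort.subjects["delta"]
    out = {
        "n_subjects": int(cohort.n_subjects),
        "visits_mean": float(counts.mean()),
        "visits_sd": float(counts.std(ddof=1)),
        "visits_min": int(counts.min()),
        "visits_max": int(counts.max()),
        "prop_dementia": float((delta == 1).mean()),
        "prop_death": float((delta == 2).mean()),
        "n_mri": int(cohort.subjects["wm_svid"].notna().sum())
        if "wm_svid" in cohort.subjects else 0,
    }
    if truth is not None:
        merged = cohort.visits.merge(
            truth[["subject_id", "true_class"]], on="subject_id")
        first = merged.sort_values("t").groupby("subject_id").first()
        out["baseline_gds_by_class"] = (
            first.groupby("true_class")["y"].mean().to_dict())
    return out


def generate_class_exposure_sample(n: int, log_or: np.ndarray,
                                   class_logits: np.ndarray,
                                   seed: int = 0) -> pd.DataFrame:
    """Class labels with a planted per-SD exposure effect.

    Draws a standard-normal exposure ``x`` and assigns each subject a class
    from the multinomial logit ``log P(g)/P(ref) = logit_g + log_or_g * x``
    (reference class first, ``log_or[0] = 0``).  Used to check that the
    weighted multinomial regression recovers a known per-SD odds ratio.
    """
    log_or = np.asarray(log_or, dtype=float)
    class_logits = np.asarray(class_logits, dtype=float)
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    eta = class_logits[None, :] + np.outer(x, log_or)
    p = np.exp(eta - eta.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    cls = np.array([rng.choice(len(log_or), p=row) for row in p])
    return pd.DataFrame({"exposure": x, "class": cls})
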