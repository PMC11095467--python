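import numpy as np
import pytest

from jlcmm import FitConfig, default_scenario, fit_jlcmm, generate_cohort
from jlcmm.synthetic import ScenarioConfig


def two_class_scenario(n=300):
    """Well-separated two-class scenario for recovery tests."""
    return ScenarioConfig(
        n_subjects=n,
        class_names=["low", "high"],
        pi=[0.6, 0.4],
        intercept=[1.0, 8.0],
        slope_pre=[0.0, 0.1],
        slope_post=[0.0, 0.2],
        sigma_b=0.8,
        sigma_e=1.0,
        log_hr_dementia=[0.0, float(np.log(2.0))],
        log_hr_death=[0.0, 0.0],
        age_mean=[72.0, 73.0],
        age_sd=[3.0, 3.0],
        history_depression_prev=[0.05, 0.2],
        wm_svid_mean=[2.5, 5.0],
        wm_svid_sd=[3.5, 6.0],
        adps_mean=[0.23, 0.33],
        adps_sd=[0.16, 0.2],
    )


@pytest.fixture(scope="session")
def small_cohort():
    sc = default_scenario()
    sc.n_subjects = 150
    return generate_cohort(sc, seed=7)


@pytest.fixture(scope="session")
def fitted5():
    """Five-class fit of a moderate default-scenario cohort, reused by the
    reporting and posterior tests."""
    sc = default_scenario()
    sc.n_subjects = 2000
    cohort, truth = generate_cohort(sc, seed=11)
    cfg = FitConfig(n_starts=10, short_run_iters=25, seed=11)
    model = fit_jlcmm(cohort, 5, cfg)
    return cohort, truth, model
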