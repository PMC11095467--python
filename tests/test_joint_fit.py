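"""Joint likelihood, optimization, posteriors, enumeration, hazard ratios."""

import numpy as np
import pandas as pd
import pytest

from jlcmm import (FitConfig, class_hazard_ratios, enumerate_classes,
                   fit_jlcmm, joint_loglik, posterior_class_probs)
from jlcmm.fit import FittedModel, ModelParams
from jlcmm.membership import MembershipParams, class_prior
from jlcmm.survival import SurvivalParams, survival_loglik
from jlcmm.synthetic import ScenarioConfig, generate_cohort
from jlcmm.trajectory import (ClassTrajectoryParams, TrajectoryCommonParams,
                              longitudinal_loglik)

from conftest import two_class_scenario


def _toy_cohort(n=10, seed=0, G=2):
    sc = two_class_scenario(n) if G == 2 else ScenarioConfig(n_subjects=n)
    return generate_cohort(sc, seed=seed)


def _manual_params(G=2):
    classes = [ClassTrajectoryParams(1.0 + 4.0 * g, 0.05 * g, 0.1 * g)
               for g in range(G)]
    common = TrajectoryCommonParams(np.zeros(0), sigma_b=0.9, sigma_e=1.1)
    zeta = np.zeros((G, 2))
    zeta[1:, 0] = 0.6
    surv = SurvivalParams(np.array([1.6, 1.2]), np.array([20.0, 25.0]), zeta)
    theta = np.zeros(G)
    theta[1:] = -0.4
    return ModelParams(None, classes, common, surv, MembershipParams(theta))


def _per_subject_components(cohort, params):
    """Independent dense evaluation: loop subjects/classes through the
    component modules."""
    out = []
    for _, srow in cohort.subjects.iterrows():
        v = cohort.visits[cohort.visits["subject_id"] == srow["subject_id"]]
        row = []
        for g in range(params.G):
            ll = longitudinal_loglik(v["t"].to_numpy(), v["y"].to_numpy(),
                                     [], params.classes[g], params.common,
                                     params.link)
            ll += survival_loglik(float(srow["T"]), int(srow["delta"]), g,
                                  [], params.survival)
            row.append(ll)
        out.append(row)
    return np.array(out)


class TestJointLoglik:
    def test_one_class_equals_component_sum(self):
        cohort, _ = _toy_cohort(8, seed=3)
        params = _manual_params(G=1)
        comp = _per_subject_components(cohort, params)
        assert joint_loglik(cohort, params) == pytest.approx(
            comp.sum(), abs=1e-9)

    def test_duplicated_classes_leave_likelihood_unchanged(self):
        cohort, _ = _toy_cohort(8, seed=3)
        p1 = _manual_params(G=1)
        classes = [p1.classes[0], ClassTrajectoryParams(
            p1.classes[0].beta0, p1.classes[0].beta1, p1.classes[0].beta2)]
        p2 = ModelParams(None, classes, p1.common,
                         SurvivalParams(p1.survival.alpha, p1.survival.sigma,
                                        np.zeros((2, 2))),
                         MembershipParams(np.zeros(2)))
        assert joint_loglik(cohort, p2) == pytest.approx(
            joint_loglik(cohort, p1), abs=1e-9)

    def test_matches_brute_force_mixture_on_toy_cohort(self):
        cohort, _ = _toy_cohort(10, seed=5)
        params = _manual_params(G=2)
        comp = _per_subject_components(cohort, params)
        log_pi = np.log(class_prior(params.membership))
        oracle = sum(
            np.logaddexp.reduce(log_pi + comp[i]) for i in range(10))
        assert joint_loglik(cohort, params) == pytest.approx(oracle,
                                                             abs=1e-10)

    def test_empty_class_leaves_likelihood_unchanged(self):
        cohort, _ = _toy_cohort(8, seed=3)
        p1 = _manual_params(G=2)
        classes = p1.classes + [ClassTrajectoryParams(9.0, 0.0, 0.0)]
        zeta = np.vstack([p1.survival.zeta, [2.0, 0.0]])
        theta = np.r_[p1.membership.theta, -40.0]
        p3 = ModelParams(None, classes, p1.common,
                         SurvivalParams(p1.survival.alpha, p1.survival.sigma,
                                        zeta), MembershipParams(theta))
        assert joint_loglik(cohort, p3) == pytest.approx(
            joint_loglik(cohort, p1), abs=1e-8)

    def test_degenerate_link_names_offending_subject(self):
        from jlcmm.link import LinkParams

        cohort, _ = _toy_cohort(5, seed=1)
        params = _manual_params(G=1)
        bad_link = LinkParams([0, 7.5, 15],
                              eta=np.array([0.0, 0.0, 1.0, 1.0]))
        bad = ModelParams(bad_link, params.classes, params.common,
                          params.survival, params.membership)
        with pytest.raises(ValueError, match="subject"):
            joint_loglik(cohort, bad)


class TestFit:
    def test_same_seed_reproduces_loglik_bit_identically(self):
        cohort, _ = _toy_cohort(120, seed=2)
        cfg = FitConfig(n_starts=3, short_run_iters=10, seed=42)
        m1 = fit_jlcmm(cohort, 2, cfg)
        m2 = fit_jlcmm(cohort, 2, cfg)
        assert m1.loglik == m2.loglik
        np.testing.assert_array_equal(m1.posterior, m2.posterior)

    def test_well_separated_two_class_recovery(self):
        sc = two_class_scenario(500)
        cohort, truth = generate_cohort(sc, seed=13)
        m = fit_jlcmm(cohort, 2, FitConfig(n_starts=5, short_run_iters=15,
                                           seed=13))
        acc = (m.modal_class == truth["true_class"].to_numpy()).mean()
        assert acc >= 0.95

    def test_bic_recomputes_from_definition(self):
        cohort, _ = _toy_cohort(100, seed=6)
        m = fit_jlcmm(cohort, 2, FitConfig(n_starts=3, short_run_iters=10,
                                           seed=0))
        assert m.bic == pytest.approx(
            -2.0 * m.loglik + m.n_params * np.log(cohort.n_subjects))

    def test_relabeling_orders_classes_by_score_at_centering_time(self):
        sc = two_class_scenario(300)
        cohort, _ = generate_cohort(sc, seed=17)
        m = fit_jlcmm(cohort, 2, FitConfig(n_starts=4, short_run_iters=10,
                                           seed=17))
        b0 = [c.beta0 for c in m.params.classes]
        assert b0[0] < b0[1]

    def test_one_class_weibull_matches_lifelines(self, small_cohort):
        """G = 1 survival estimates agree with per-cause Weibull fits from
        an independent survival package (other cause treated as censoring)."""
        from lifelines import WeibullFitter

        cohort, _ = small_cohort
        m = fit_jlcmm(cohort, 1, FitConfig(link_mode="identity", seed=0))
        T = cohort.subjects["T"].to_numpy()
        delta = cohort.subjects["delta"].to_numpy()
        for k in range(2):
            wf = WeibullFitter()
            wf.fit(T, event_observed=(delta == k + 1))
            assert m.params.survival.alpha[k] == pytest.approx(
                wf.rho_, rel=1e-3)
            assert m.params.survival.sigma[k] == pytest.approx(
                wf.lambda_, rel=1e-3)


class TestPosterior:
    def test_single_class_posterior_is_one(self):
        cohort, _ = _toy_cohort(30, seed=8)
        m = fit_jlcmm(cohort, 1, FitConfig(seed=0))
        np.testing.assert_allclose(m.posterior, 1.0)

    def test_rows_sum_to_one(self, fitted5):
        _, _, m = fitted5
        np.testing.assert_allclose(m.posterior.sum(axis=1), 1.0, atol=1e-10)

    def test_matches_bayes_rule_on_toy_cohort(self):
        cohort, _ = _toy_cohort(5, seed=9)
        params = _manual_params(G=2)
        fitted = FittedModel(params=params, loglik=0.0, n_params=0, bic=0.0,
                             posterior=None, modal_class=None,
                             subject_ids=None, convergence={}, config=None)
        post = posterior_class_probs(fitted, cohort)
        comp = _per_subject_components(cohort, params)
        num = comp + np.log(class_prior(params.membership))
        oracle = np.exp(num - np.logaddexp.reduce(num, axis=1)[:, None])
        np.testing.assert_allclose(post, oracle, atol=1e-10)


class TestEnumeration:
    def test_single_class_generator_selects_one_class(self):
        sc = two_class_scenario(150)
        sc.pi = [1.0 - 1e-12, 1e-12]  # effectively one class
        sc.pi = [0.5, 0.5]
        sc.intercept = [3.0, 3.0]  # identical classes: no real structure
        sc.slope_pre = [0.0, 0.0]
        sc.slope_post = [0.0, 0.0]
        sc.log_hr_dementia = [0.0, 0.0]
        cohort, _ = generate_cohort(sc, seed=19)
        table, best = enumerate_classes(
            cohort, 2, FitConfig(n_starts=3, short_run_iters=10, seed=19))
        assert best.G == 1
        assert bool(table.loc[table["G"] == 1, "selected"].iloc[0])

    def test_two_class_structure_detected(self):
        sc = two_class_scenario(300)
        cohort, _ = generate_cohort(sc, seed=23)
        table, best = enumerate_classes(
            cohort, 3, FitConfig(n_starts=4, short_run_iters=15, seed=23))
        assert best.G == 2
        # maximized likelihood is nondecreasing in G
        ll = table["loglik"].to_numpy()
        assert np.all(np.diff(ll) > -1e-6)


class TestHazardRatios:
    def test_planted_log_hazard_ratio_recovered(self):
        sc = two_class_scenario(600)
        cohort, truth = generate_cohort(sc, seed=29)
        m = fit_jlcmm(cohort, 2, FitConfig(n_starts=4, short_run_iters=15,
                                           seed=29))
        hr = class_hazard_ratios(m)
        dem = hr[(hr["cause"] == "dementia") & (hr["class"] == 1)].iloc[0]
        n_events = int((cohort.subjects["delta"] == 1).sum())
        se_plant = np.sqrt(4.0 / n_events)
        assert abs(dem["log_hr"] - np.log(2.0)) < 3 * se_plant
        assert dem["ci_available"]
        assert dem["ci_lo"] < dem["hr"] < dem["ci_hi"]

    def test_requires_at_least_two_classes(self):
        cohort, _ = _toy_cohort(30, seed=8)
        m = fit_jlcmm(cohort, 1, FitConfig(seed=0))
        with pytest.raises(ValueError, match="two classes"):
            class_hazard_ratios(m)
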