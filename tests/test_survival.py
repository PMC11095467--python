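"""Weibull competing-risks component: hazards, likelihood, incidence."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import minimize

from jlcmm.survival import (SurvivalParams, cause_hazard, cumulative_hazard,
                            cumulative_incidence, survival_loglik)


def _params(alpha=(1.0, 1.0), sigma=(1.0, 1.0), zeta=None, G=2):
    if zeta is None:
        zeta = np.zeros((G, 2))
    return SurvivalParams(np.asarray(alpha), np.asarray(sigma), zeta)


class TestHazard:
    def test_shape_one_gives_constant_hazard(self):
        p = _params(alpha=(1.0, 1.0), sigma=(2.0, 1.0))
        t = np.array([0.5, 1.0, 5.0])
        np.testing.assert_allclose(cause_hazard(t, 0, 0, [], p), 0.5)

    def test_log_hazard_ratio_scales_hazard_proportionally(self):
        zeta = np.array([[0.0, 0.0], [np.log(2.0), 0.0]])
        p = _params(alpha=(1.7, 1.0), sigma=(3.0, 1.0), zeta=zeta)
        t = np.linspace(0.1, 10, 25)
        np.testing.assert_allclose(cause_hazard(t, 0, 1, [], p),
                                   2.0 * cause_hazard(t, 0, 0, [], p))

    def test_closed_form_cumulative_hazard_matches_quadrature(self):
        zeta = np.array([[0.0, 0.0], [0.4, -0.2]])
        p = SurvivalParams(np.array([1.8, 0.9]), np.array([12.0, 20.0]),
                           zeta, omega=np.array([[0.3], [-0.1]]))
        w = np.array([1.2])
        for cause in (0, 1):
            num, _ = quad(lambda u: cause_hazard(u, cause, 1, w, p),
                          0.0, 7.3, epsabs=1e-12, limit=200)
            closed = cumulative_hazard(7.3, cause, 1, w, p)
            assert num == pytest.approx(float(closed), abs=1e-8)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError, match="t > 0"):
            cause_hazard(0.0, 0, 0, [], _params())


class TestLoglik:
    def test_double_exponential_censored_subject(self):
        # unit-rate exponential for both causes, censored at T=1: -2
        p = _params(alpha=(1.0, 1.0), sigma=(1.0, 1.0))
        assert survival_loglik(1.0, 0, 0, [], p) == pytest.approx(-2.0)

    def test_single_active_cause_event(self):
        # cause 1 unit rate, cause 2 rate ~0: log h(1) - Lambda(1) = -1
        p = _params(alpha=(1.0, 1.0), sigma=(1.0, 1e8))
        assert survival_loglik(1.0, 1, 0, [], p) == pytest.approx(-1.0,
                                                                  abs=1e-6)

    def test_shape_one_equals_exponential_closed_form(self):
        rng = np.random.default_rng(2)
        p = _params(alpha=(1.0, 1.0), sigma=(4.0, 7.0),
                    zeta=np.array([[0.0, 0.0], [0.5, -0.3]]))
        for _ in range(20):
            T = rng.uniform(0.2, 10)
            delta = rng.integers(0, 3)
            g = rng.integers(0, 2)
            r1 = np.exp(p.zeta[g, 0]) / 4.0
            r2 = np.exp(p.zeta[g, 1]) / 7.0
            expect = -(r1 + r2) * T
            if delta == 1:
                expect += np.log(r1)
            elif delta == 2:
                expect += np.log(r2)
            assert survival_loglik(T, int(delta), int(g), [], p) == \
                pytest.approx(expect, abs=1e-10)

    def test_invalid_delta_rejected(self):
        with pytest.raises(ValueError, match="delta"):
            survival_loglik(1.0, 3, 0, [], _params())

    def test_mle_recovers_planted_parameters(self):
        """Joint MLE on simulated competing-risks times lands within 3
        standard errors of the planted shapes, scales and log-HR."""
        rng = np.random.default_rng(15)
        n = 4000
        true = dict(a1=1.6, s1=12.0, a2=1.1, s2=15.0, z=0.7)
        g = (rng.uniform(size=n) < 0.5).astype(int)
        u = rng.uniform(size=(n, 2))
        t1 = true["s1"] * (-np.log(u[:, 0]) / np.exp(true["z"] * g)) ** (
            1 / true["a1"])
        t2 = true["s2"] * (-np.log(u[:, 1])) ** (1 / true["a2"])
        C = 10.0
        T = np.minimum(np.minimum(t1, t2), C)
        delta = np.where(T == t1, 1, np.where(T == t2, 2, 0))

        def nll(x):
            p = SurvivalParams(np.exp(x[:2]), np.exp(x[2:4]),
                               np.array([[0.0, 0.0], [x[4], 0.0]]))
            # vectorized closed form (same algebra the module implements)
            ll = 0.0
            for k in range(2):
                lp = p.zeta[g, k]
                lam = (T / p.sigma[k]) ** p.alpha[k] * np.exp(lp)
                ll -= lam.sum()
                ev = delta == k + 1
                ll += (np.log(p.alpha[k] / p.sigma[k])
                       + (p.alpha[k] - 1)
                       * np.log(T[ev] / p.sigma[k]) + lp[ev]).sum()
            return -ll

        res = minimize(nll, np.zeros(5), method="Nelder-Mead",
                       options={"maxiter": 4000, "xatol": 1e-8,
                                "fatol": 1e-10})
        a1, a2 = np.exp(res.x[:2])
        s1, s2 = np.exp(res.x[2:4])
        z = res.x[4]
        # the module's per-subject loglik agrees with the vectorized
        # closed form used for the MLE
        p_hat = SurvivalParams(np.array([a1, a2]), np.array([s1, s2]),
                               np.array([[0.0, 0.0], [z, 0.0]]))
        module = sum(survival_loglik(float(T[i]), int(delta[i]), int(g[i]),
                                     [], p_hat) for i in range(n))
        assert module == pytest.approx(-nll(res.x), rel=1e-10)
        # recovery within 3 SE (SE ~ 1/sqrt(events))
        n1, n2 = (delta == 1).sum(), (delta == 2).sum()
        assert abs(a1 - true["a1"]) < 3 * true["a1"] / np.sqrt(n1)
        assert abs(a2 - true["a2"]) < 3 * true["a2"] / np.sqrt(n2)
        assert abs(z - true["z"]) < 3 * np.sqrt(4 / n1)


class TestCumulativeIncidence:
    def test_single_cause_matches_closed_form(self):
        p = _params(alpha=(1.4, 1.0), sigma=(5.0, 1e9))
        t = np.linspace(0.0, 12, 40)
        cif = cumulative_incidence(t, 0, [], p)
        closed = 1.0 - np.exp(-(t / 5.0) ** 1.4)
        np.testing.assert_allclose(cif[:, 0], closed, atol=1e-6)

    def test_probability_is_conserved(self):
        zeta = np.array([[0.0, 0.0], [0.8, 0.3]])
        p = _params(alpha=(1.9, 1.2), sigma=(9.0, 14.0), zeta=zeta)
        t = np.linspace(0.0, 13, 30)
        for g in (0, 1):
            cif = cumulative_incidence(t, g, [], p)
            S = np.exp(-sum(cumulative_hazard(np.maximum(t, 1e-12), k, g, [],
                                              p) for k in range(2)))
            np.testing.assert_allclose(cif.sum(axis=1) + S, 1.0, atol=1e-6)

    def test_equal_cause_hazards_give_identical_curves(self):
        p = _params(alpha=(1.5, 1.5), sigma=(8.0, 8.0))
        cif = cumulative_incidence(np.linspace(0, 10, 20), 0, [], p)
        np.testing.assert_allclose(cif[:, 0], cif[:, 1], atol=1e-10)

    def test_curves_nondecreasing_and_bounded(self):
        p = _params(alpha=(2.2, 0.8), sigma=(10.0, 18.0))
        cif = cumulative_incidence(np.linspace(0, 13, 50), 0, [], p)
        assert np.all(np.diff(cif, axis=0) >= -1e-12)
        assert cif.max() <= 1.0

    def test_higher_dementia_hazard_raises_dementia_incidence(self):
        t = np.linspace(0.5, 13, 20)
        base = _params(alpha=(1.8, 1.3), sigma=(12.0, 16.0))
        raised = _params(alpha=(1.8, 1.3), sigma=(12.0, 16.0),
                         zeta=np.array([[0.0, 0.0], [0.9, 0.0]]))
        c0 = cumulative_incidence(t, 0, [], base)[:, 0]
        c1 = cumulative_incidence(t, 1, [], raised)[:, 0]
        assert np.all(c1 > c0)
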