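"""Cause-specific Weibull proportional hazards for dementia and death.

Dementia (cause 1) and death without prior dementia (cause 2) compete: the
observed outcome per subject is ``(T, delta)`` with ``delta`` 0 for
censoring, 1 for dementia, 2 for death.  Each cause k has a two-parameter
Weibull baseline hazard

    h_k0(t) = (alpha_k / sigma_k) * (t / sigma_k) ** (alpha_k - 1),

multiplied proportionally by ``exp(zeta_gk + w' omega_k)`` where ``zeta_gk``
is the log hazard ratio of latent class g versus the reference class
(``zeta_ref,k = 0``) and ``omega_k`` are covariate effects.  The cumulative
hazard is closed form, ``Lambda_k(t) = (t / sigma_k)^alpha_k * exp(lp)``,
so the cause-specific likelihood needs no quadrature; quadrature appears
only in the cumulative incidence functions, which integrate
``h_k(u) * S(u)`` with the all-cause survival ``S``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_simpson

__all__ = [
    "SurvivalParams",
    "cause_hazard",
    "cumulative_hazard",
    "survival_loglik",
    "cumulative_incidence",
]

CAUSES = ("dementia", "death")


@dataclass
class SurvivalParams:
    """Weibull PH parameters; arrays indexed by cause (dementia, death)."""

    alpha: np.ndarray  # shapes, > 0
    sigma: np.ndarray  # scales (years), > 0
    zeta: np.ndarray   # (G, 2) class log-HRs, row of the reference class = 0
    omega: np.ndarray = field(default_factory=lambda: np.zeros((2, 0)))

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.zeta = np.atleast_2d(np.asarray(self.zeta, dtype=float))
        self.omega = np.atleast_2d(np.asarray(self.omega, dtype=float))
        if self.alpha.shape != (2,) or self.sigma.shape != (2,):
            raise ValueError("alpha and sigma must have one entry per cause")
        if np.any(self.alpha <= 0) or np.any(self.sigma <= 0):
            raise ValueError("Weibull shape and scale must be positive")
        if self.zeta.shape[1] != 2:
            raise ValueError("zeta must have two columns (dementia, death)")

    @property
    def n_classes(self) -> int:
        return self.zeta.shape[0]


def _linear_predictor(g, w, params: SurvivalParams, cause: int) -> float:
    lp = params.zeta[g, cause]
    w = np.asarray(w, dtype=float)
    if params.omega.shape[1]:
        lp = lp + float(np.dot(w, params.omega[cause]))
    return lp


def cause_hazard(t, cause: int, g: int, w, params: SurvivalParams):
    """Hazard rate of one cause (per year) at times ``t > 0``."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("hazard defined for t > 0 only")
    a, s = params.alpha[cause], params.sigma[cause]
    lp = _linear_predictor(g, w, params, cause)
    return (a / s) * (t / s) ** (a - 1.0) * np.exp(lp)


def cumulative_hazard(t, cause: int, g: int, w, params: SurvivalParams):
    """Closed-form Weibull cumulative hazard ``Lambda_k(t)``."""
    t = np.asarray(t, dtype=float)
    a, s = params.alpha[cause], params.sigma[cause]
    lp = _linear_predictor(g, w, params, cause)
    return (t / s) ** a * np.exp(lp)


def survival_loglik(T: float, delta: int, g: int, w,
                    params: SurvivalParams) -> float:
    """Cause-specific competing-risks log-likelihood of one subject.

    ``log h_delta(T) - sum_k Lambda_k(T)``; the hazard term is dropped for
    censored subjects (delta = 0).
    """
    if delta not in (0, 1, 2):
        raise ValueError(f"delta must be 0, 1 or 2; got {delta}")
    if T <= 0:
        raise ValueError("event/censoring time must be positive")
    ll = 0.0
    if delta:
        ll += float(np.log(cause_hazard(T, delta - 1, g, w, params)))
    for k in range(2):
        ll -= float(cumulative_hazard(T, k, g, w, params))
    return ll


def cumulative_incidence(t_grid, g: int, w, params: SurvivalParams,
                         refine: int = 64):
    """Cumulative incidence of each cause on ``t_grid``.

    CIF_k(t) = int_0^t h_k(u) S(u) du with S the all-cause survival, by
    composite Simpson quadrature under the substitution u = v^3 (which
    removes the singular derivative of the Weibull hazard at the origin),
    interpolated back onto ``t_grid``.  Returns an array ``(len(t_grid), 2)``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0) or np.any(t_grid < 0):
        raise ValueError("t_grid must be increasing and nonnegative")
    hi = t_grid[-1]
    v = np.linspace(0.0, hi ** (1.0 / 3.0), refine * len(t_grid) + 1)
    u = v**3
    u_pos = np.maximum(u, 1e-300)
    Lam = np.stack(
        [cumulative_hazard(u_pos, k, g, w, params) for k in range(2)], axis=1
    )
    S = np.exp(-Lam.sum(axis=1))
    out = np.empty((len(t_grid), 2))
    for k in range(2):
        # h_k(v^3) * S * 3 v^2, written to stay finite at v = 0 for any
        # shape >= 1/3
        a = params.alpha[k]
        s = params.sigma[k]
        lp = params.zeta[g, k]
        if params.omega.shape[1]:
            lp = lp + float(np.dot(np.asarray(w, dtype=float),
                                   params.omega[k]))
        integrand = (3.0 * a / s * np.exp(lp)
                     * v ** (3.0 * a - 1.0) / s ** (a - 1.0) * S)
        cif = cumulative_simpson(integrand, x=v, initial=0.0)
        out[:, k] = np.interp(t_grid, u, cif)
    return np.clip(out, 0.0, 1.0)
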