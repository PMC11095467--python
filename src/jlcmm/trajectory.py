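"""Class-specific piecewise-linear mixed model for the transformed score.

Each latent class g has a mean trajectory on the transformed scale

    mu_ij(g) = beta0_g + beta1_g * min(t_ij, 0) + beta2_g * max(t_ij, 0)
               + x_ij' gamma,

i.e. a piecewise-linear curve with a kink at the centering time t = 0 (the
late-study baseline, or age 80 in the age-scale sensitivity analysis).
``beta1_g`` is the slope across mid-older adulthood, ``beta2_g`` the slope
across late-older adulthood, and ``beta0_g`` the level at the inflection
point.  Covariate effects ``gamma`` are shared across classes.

Subjects carry a single Gaussian random intercept, so the within-subject
covariance is compound-symmetric: ``Sigma_i = sigma_e^2 I + sigma_b^2 J``.
The marginal likelihood is evaluated in closed form with the rank-one
determinant and inverse identities — no numerical integration and no dense
matrix factorisation per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .link import LinkParams, evaluate_link

__all__ = [
    "ClassTrajectoryParams",
    "TrajectoryCommonParams",
    "class_mean",
    "longitudinal_loglik",
    "piecewise_design",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class ClassTrajectoryParams:
    beta0: float  # level at the centering time
    beta1: float  # slope per year before t = 0
    beta2: float  # slope per year from t = 0 on


@dataclass
class TrajectoryCommonParams:
    gamma: np.ndarray = field(default_factory=lambda: np.zeros(0))
    sigma_b: float = 0.5  # random-intercept SD
    sigma_e: float = 1.0  # residual SD; fixed to 1 under the spline link

    def __post_init__(self):
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.sigma_b < 0:
            raise ValueError("sigma_b must be nonnegative")
        if self.sigma_e <= 0:
            raise ValueError("sigma_e must be positive")


def piecewise_design(t):
    """Design columns ``[1, min(t,0), max(t,0)]`` for the kinked trajectory."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    return np.column_stack(
        [np.ones_like(t), np.minimum(t, 0.0), np.maximum(t, 0.0)]
    )


def class_mean(t, x, class_params: ClassTrajectoryParams,
               common: TrajectoryCommonParams):
    """Mean transformed score at times ``t`` with covariate row ``x``."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    D = piecewise_design(t)
    b = np.array([class_params.beta0, class_params.beta1, class_params.beta2])
    mu = D @ b
    x = np.asarray(x, dtype=float)
    if x.size != common.gamma.size:
        raise ValueError(
            f"covariate length {x.size} does not match gamma length "
            f"{common.gamma.size}"
        )
    if common.gamma.size:
        mu = mu + float(np.dot(x, common.gamma))
    return mu


def _compound_symmetric_loglik(r, sigma_b, sigma_e):
    """log N(r; 0, sigma_e^2 I + sigma_b^2 J) via rank-one identities."""
    n = r.size
    ve = sigma_e**2
    vb = sigma_b**2
    denom = ve + n * vb
    logdet = (n - 1) * np.log(ve) + np.log(denom)
    s = r.sum()
    quad = (r @ r - vb * s * s / denom) / ve
    return -0.5 * (n * _LOG2PI + logdet + quad)


def longitudinal_loglik(t, y, x, class_params: ClassTrajectoryParams,
                        common: TrajectoryCommonParams,
                        link_params: LinkParams | None) -> float:
    """Marginal log-likelihood of one subject's visits under one class.

    The observed scores are pushed through the link; the Jacobian term
    ``sum_j log H'(y_ij)`` makes likelihoods comparable across link
    parameter values.  ``link_params=None`` means the identity link (raw
    scores, no Jacobian).
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if t.size == 0:
        raise ValueError("subject has no visits")
    if link_params is None:
        h, jac = y, 0.0
    else:
        h, dh = evaluate_link(y, link_params)
        if np.any(dh <= 0):
            return -np.inf
        jac = float(np.log(dh).sum())
    mu = class_mean(t, x, class_params, common)
    return _compound_symmetric_loglik(h - mu, common.sigma_b,
                                      common.sigma_e) + jac
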