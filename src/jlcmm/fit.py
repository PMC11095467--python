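"""Joint likelihood assembly, maximization, class enumeration, posteriors.

The joint latent class mixture model couples three components through a
finite mixture over G latent classes:

    L_i = sum_g pi_g * f_long(y_i | g) * f_surv(T_i, delta_i | g)

with class-conditional independence of the longitudinal and survival parts.
``f_long`` is the marginal multivariate-normal density of the spline-
transformed scores under the class trajectory (random intercept, closed
form), ``f_surv`` the cause-specific Weibull competing-risks likelihood.
The observed-data log-likelihood is maximized directly by quasi-Newton
(L-BFGS) with finite-difference gradients: every class-conditional factor
is closed form, so no EM or numerical integration is needed.  Multi-start
(short perturbed runs seeded from the one-class solution) guards against
local optima; classes are relabeled deterministically by their model-implied
score at the centering time so reported output is unique.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax

from .cohort import CohortData
from .link import LinkBasis, LinkParams, fit_link_knots, invert_link
from .membership import MembershipParams, class_prior
from .survival import SurvivalParams
from .trajectory import (ClassTrajectoryParams, TrajectoryCommonParams,
                         piecewise_design)

logger = logging.getLogger(__name__)

__all__ = [
    "ModelParams",
    "FitConfig",
    "FittedModel",
    "FitData",
    "build_fit_data",
    "joint_loglik",
    "fit_jlcmm",
    "posterior_class_probs",
    "enumerate_classes",
    "class_hazard_ratios",
]

_LOG2PI = np.log(2.0 * np.pi)
_BIG = 1e10


@dataclass
class ModelParams:
    """All parameters of a G-class joint model."""

    link: LinkParams | None  # None = identity link (raw-score model)
    classes: list  # list of ClassTrajectoryParams, length G
    common: TrajectoryCommonParams
    survival: SurvivalParams
    membership: MembershipParams

    @property
    def G(self) -> int:
        return len(self.classes)

    def __post_init__(self):
        if self.survival.n_classes != self.G:
            raise ValueError("survival zeta rows must match class count")
        if self.membership.n_classes != self.G:
            raise ValueError("membership logits must match class count")

    def to_dict(self) -> dict:
        """JSON-serializable summary of all parameters."""
        link = None
        if self.link is not None:
            link = {"knots": self.link.knots.tolist(),
                    "eta0": float(self.link.eta0),
                    "eta": self.link.eta.tolist()}
        return {
            "G": self.G,
            "link": link,
            "classes": [{"beta0": c.beta0, "beta1": c.beta1,
                         "beta2": c.beta2} for c in self.classes],
            "gamma": self.common.gamma.tolist(),
            "sigma_b": float(self.common.sigma_b),
            "sigma_e": float(self.common.sigma_e),
            "weibull_shape": self.survival.alpha.tolist(),
            "weibull_scale": self.survival.sigma.tolist(),
            "zeta": self.survival.zeta.tolist(),
            "omega": self.survival.omega.tolist(),
            "theta": self.membership.theta.tolist(),
        }


@dataclass
class FitConfig:
    n_starts: int = 30
    short_run_iters: int = 15
    max_iters: int = 500
    ftol: float = 1e-10
    gtol: float = 1e-5
    seed: int = 0
    perturb_scale: float = 1.0
    link_mode: str = "spline"  # "spline" or "identity"
    n_knots: int = 3

    def __post_init__(self):
        if self.n_starts < 1 or self.short_run_iters < 1 or self.max_iters < 1:
            raise ValueError("iteration counts must be positive")
        if self.ftol <= 0 or self.gtol <= 0:
            raise ValueError("tolerances must be positive")
        if self.link_mode not in ("spline", "identity"):
            raise ValueError("link_mode must be 'spline' or 'identity'")


@dataclass
class FittedModel:
    params: ModelParams
    loglik: float
    n_params: int
    bic: float
    posterior: np.ndarray  # (N, G)
    modal_class: np.ndarray  # (N,)
    subject_ids: np.ndarray
    convergence: dict
    config: FitConfig
    _data: "FitData" = field(repr=False, default=None)

    @property
    def G(self) -> int:
        return self.params.G


# ---------------------------------------------------------------------------
# data preparation


class FitData:
    """Cohort flattened into arrays for fast repeated likelihood evaluation."""

    def __init__(self, cohort: CohortData, link_mode: str = "spline",
                 n_knots: int = 3, knots=None):
        subjects = cohort.subjects.reset_index(drop=True)
        order = {sid: i for i, sid in enumerate(subjects["subject_id"])}
        visits = cohort.visits.copy()
        visits["_ix"] = visits["subject_id"].map(order)
        if visits["_ix"].isna().any():
            raise ValueError("visit references unknown subject")
        visits = visits.sort_values(["_ix", "t"], kind="mergesort")

        self.subject_ids = subjects["subject_id"].to_numpy()
        self.N = len(subjects)
        idx = visits["_ix"].to_numpy(dtype=int)
        counts = np.bincount(idx, minlength=self.N)
        if np.any(counts == 0):
            raise ValueError("every subject needs at least one visit")
        self.n_i = counts
        self.starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        self.t = visits["t"].to_numpy(dtype=float)
        self.y = visits["y"].to_numpy(dtype=float)
        self.D = piecewise_design(self.t)
        self.Xl = _design_matrix(visits, cohort.schema.long_covariates,
                                 cohort.schema.categorical)
        self.T = subjects["T"].to_numpy(dtype=float)
        self.delta = subjects["delta"].to_numpy(dtype=int)
        self.Xs = _design_matrix(subjects, cohort.schema.surv_covariates,
                                 cohort.schema.categorical)
        self.logT = np.log(self.T)
        self.link_mode = link_mode
        if link_mode == "spline":
            self.knots = (np.asarray(knots, dtype=float) if knots is not None
                          else fit_link_knots(self.y, n_knots))
            self.basis = LinkBasis(self.knots)
            self.I, self.M = self.basis.design(self.y)
        else:
            self.knots = None

    @property
    def p_long(self) -> int:
        return self.Xl.shape[1]

    @property
    def p_surv(self) -> int:
        return self.Xs.shape[1]

    def reduce(self, v):
        """Per-subject sums of a per-visit vector."""
        return np.add.reduceat(v, self.starts)


def _design_matrix(df: pd.DataFrame, columns, categorical) -> np.ndarray:
    cols = []
    for c in columns:
        if c in categorical:
            levels = list(categorical[c])
            s = df[c].astype(object).where(df[c].notna(), "missing")
            for lev in levels[1:]:
                cols.append((s == lev).to_numpy(dtype=float))
        else:
            v = df[c].to_numpy(dtype=float)
            if np.any(~np.isfinite(v)):
                raise ValueError(
                    f"missing values in continuous covariate '{c}'; exclude "
                    "those rows before fitting"
                )
            cols.append(v)
    if not cols:
        return np.zeros((len(df), 0))
    return np.column_stack(cols)


def build_fit_data(cohort: CohortData, config: FitConfig | None = None,
                   knots=None) -> FitData:
    config = config or FitConfig()
    return FitData(cohort, config.link_mode, config.n_knots, knots=knots)


# ---------------------------------------------------------------------------
# parameter packing


class _Structure:
    """Shapes of the packed parameter vector for one model configuration."""

    def __init__(self, G, n_eta, p_long, p_surv, link_mode):
        self.G, self.n_eta = G, n_eta
        self.p_long, self.p_surv = p_long, p_surv
        self.link_mode = link_mode
        n = n_eta if link_mode == "spline" else 0
        self.sl_eta = slice(0, n)
        self.sl_beta = slice(n, n + 3 * G)
        n += 3 * G
        self.sl_gamma = slice(n, n + p_long)
        n += p_long
        self.ix_lsb = n
        n += 1
        if link_mode == "identity":
            self.ix_lse = n
            n += 1
        else:
            self.ix_lse = None
        self.sl_lalpha = slice(n, n + 2)
        n += 2
        self.sl_lsigma = slice(n, n + 2)
        n += 2
        self.sl_zeta = slice(n, n + 2 * (G - 1))
        n += 2 * (G - 1)
        self.sl_omega = slice(n, n + 2 * p_surv)
        n += 2 * p_surv
        self.sl_theta = slice(n, n + (G - 1))
        n += G - 1
        self.n_params = n

    def unpack(self, x, knots=None) -> ModelParams:
        G = self.G
        link = None
        if self.link_mode == "spline":
            link = LinkParams(knots, 0.0, np.array(x[self.sl_eta]))
        beta = np.array(x[self.sl_beta]).reshape(3, G)
        classes = [ClassTrajectoryParams(*beta[:, g]) for g in range(G)]
        sigma_e = 1.0 if self.ix_lse is None else float(np.exp(x[self.ix_lse]))
        common = TrajectoryCommonParams(np.array(x[self.sl_gamma]),
                                        float(np.exp(x[self.ix_lsb])), sigma_e)
        zeta = np.zeros((G, 2))
        if G > 1:
            z = np.array(x[self.sl_zeta]).reshape(2, G - 1)
            zeta[1:, 0], zeta[1:, 1] = z[0], z[1]
        surv = SurvivalParams(np.exp(x[self.sl_lalpha]),
                              np.exp(x[self.sl_lsigma]), zeta,
                              np.array(x[self.sl_omega]).reshape(2, self.p_surv))
        theta = np.zeros(G)
        if G > 1:
            theta[1:] = x[self.sl_theta]
        return ModelParams(link, classes, common, surv,
                           MembershipParams(theta))

    def pack(self, params: ModelParams) -> np.ndarray:
        x = np.empty(self.n_params)
        if self.link_mode == "spline":
            x[self.sl_eta] = params.link.eta
        beta = np.array([[c.beta0, c.beta1, c.beta2]
                         for c in params.classes]).T
        x[self.sl_beta] = beta.ravel()
        x[self.sl_gamma] = params.common.gamma
        x[self.ix_lsb] = np.log(max(params.common.sigma_b, 1e-8))
        if self.ix_lse is not None:
            x[self.ix_lse] = np.log(params.common.sigma_e)
        x[self.sl_lalpha] = np.log(params.survival.alpha)
        x[self.sl_lsigma] = np.log(params.survival.sigma)
        if self.G > 1:
            x[self.sl_zeta] = np.concatenate(
                [params.survival.zeta[1:, 0], params.survival.zeta[1:, 1]]
            )
            x[self.sl_theta] = params.membership.theta[1:]
        x[self.sl_omega] = params.survival.omega.ravel()
        return x


def _structure_for(data: FitData, G: int) -> _Structure:
    n_eta = data.I.shape[1] if data.link_mode == "spline" else 0
    return _Structure(G, n_eta, data.p_long, data.p_surv, data.link_mode)


# ---------------------------------------------------------------------------
# likelihood


def _component_logliks(data: FitData, x, struct: _Structure):
    """Per-subject, per-class log f_long + log f_surv, and log prior.

    Returns ``(ll_mat, log_pi)`` with ``ll_mat`` of shape (N, G); entries
    may be -inf where a component degenerates.
    """
    G = struct.G
    # longitudinal
    if struct.link_mode == "spline":
        eta2 = np.asarray(x[struct.sl_eta]) ** 2
        h = data.I @ eta2
        dh = data.M @ eta2
        if np.any(dh <= 0):
            jac = None
        else:
            jac = data.reduce(np.log(dh))
        ve = 1.0
    else:
        h, jac = data.y, np.zeros(data.N)
        ve = float(np.exp(2 * x[struct.ix_lse]))
    if jac is None:
        return np.full((data.N, G), -np.inf), np.zeros(G)
    vb = float(np.exp(2 * x[struct.ix_lsb]))
    gamma = np.asarray(x[struct.sl_gamma])
    off = data.Xl @ gamma if gamma.size else 0.0
    beta = np.asarray(x[struct.sl_beta]).reshape(3, G)
    denom = ve + data.n_i * vb
    base = data.n_i * _LOG2PI + (data.n_i - 1) * np.log(ve) + np.log(denom)
    ll = np.empty((data.N, G))
    mu_all = data.D @ beta  # (n_visits, G)
    for g in range(G):
        r = h - mu_all[:, g] - off
        rs = data.reduce(r)
        rss = data.reduce(r * r)
        quad = (rss - vb * rs * rs / denom) / ve
        ll[:, g] = -0.5 * (base + quad) + jac
    # survival
    la = np.asarray(x[struct.sl_lalpha])
    ls = np.asarray(x[struct.sl_lsigma])
    alpha = np.exp(la)
    zeta = np.zeros((G, 2))
    if G > 1:
        z = np.asarray(x[struct.sl_zeta]).reshape(2, G - 1)
        zeta[1:, 0], zeta[1:, 1] = z[0], z[1]
    omega = np.asarray(x[struct.sl_omega]).reshape(2, struct.p_surv)
    wlp = data.Xs @ omega.T if struct.p_surv else np.zeros((data.N, 2))
    for g in range(G):
        surv = np.zeros(data.N)
        for k in range(2):
            lp = zeta[g, k] + wlp[:, k]
            logLam = alpha[k] * (data.logT - ls[k]) + lp
            surv -= np.exp(np.clip(logLam, -700, 700))
            ev = data.delta == k + 1
            if np.any(ev):
                surv[ev] += (la[k] - ls[k]
                             + (alpha[k] - 1.0) * (data.logT[ev] - ls[k])
                             + lp[ev])
        ll[:, g] += surv
    theta = np.zeros(G)
    if G > 1:
        theta[1:] = x[struct.sl_theta]
    log_pi = theta - logsumexp(theta)
    return ll, log_pi


def _loglik_vec(data: FitData, x, struct: _Structure) -> float:
    ll, log_pi = _component_logliks(data, x, struct)
    per_subject = logsumexp(ll + log_pi, axis=1)
    total = float(per_subject.sum())
    return total if np.isfinite(total) else -np.inf


def _value_and_grad(data: FitData, x, struct: _Structure):
    """Joint log-likelihood and its analytic gradient.

    The mixture gradient is the posterior-weighted sum of the class-
    conditional score functions; every piece (compound-symmetric Gaussian,
    Weibull PH, softmax prior, spline Jacobian) has a closed-form score, so
    the whole gradient costs about as much as one likelihood evaluation.
    """
    G = struct.G
    N = data.N
    grad = np.zeros(struct.n_params)

    # ---- forward: longitudinal pieces
    if struct.link_mode == "spline":
        eta = np.asarray(x[struct.sl_eta])
        eta2 = eta**2
        h = data.I @ eta2
        dh = data.M @ eta2
        if np.any(dh <= 0):
            return -np.inf, grad
        logdh = np.log(dh)
        jac = data.reduce(logdh)
        ve = 1.0
    else:
        h = data.y
        jac = np.zeros(N)
        ve = float(np.exp(2 * x[struct.ix_lse]))
    vb = float(np.exp(2 * x[struct.ix_lsb]))
    gamma = np.asarray(x[struct.sl_gamma])
    off = data.Xl @ gamma if gamma.size else 0.0
    beta = np.asarray(x[struct.sl_beta]).reshape(3, G)
    denom = ve + data.n_i * vb
    base = data.n_i * _LOG2PI + (data.n_i - 1) * np.log(ve) + np.log(denom)
    mu_all = data.D @ beta
    r_g = []
    s_g = []
    ll = np.empty((N, G))
    for g in range(G):
        r = h - mu_all[:, g] - off
        s = data.reduce(r)
        rss = data.reduce(r * r)
        quad = (rss - vb * s * s / denom) / ve
        ll[:, g] = -0.5 * (base + quad) + jac
        r_g.append(r)
        s_g.append(s)

    # ---- forward: survival pieces
    la = np.asarray(x[struct.sl_lalpha])
    ls = np.asarray(x[struct.sl_lsigma])
    alpha = np.exp(la)
    zeta = np.zeros((G, 2))
    if G > 1:
        z = np.asarray(x[struct.sl_zeta]).reshape(2, G - 1)
        zeta[1:, 0], zeta[1:, 1] = z[0], z[1]
    omega = np.asarray(x[struct.sl_omega]).reshape(2, struct.p_surv)
    wlp = data.Xs @ omega.T if struct.p_surv else np.zeros((N, 2))
    logT_c = [data.logT - ls[k] for k in range(2)]
    ev = [data.delta == 1, data.delta == 2]
    Lam = np.empty((N, G, 2))
    for k in range(2):
        base_k = alpha[k] * logT_c[k] + wlp[:, k]
        loghaz_k = la[k] - ls[k] + (alpha[k] - 1.0) * logT_c[k] + wlp[:, k]
        for g in range(G):
            Lam[:, g, k] = np.exp(np.clip(base_k + zeta[g, k], -700, 700))
            ll[:, g] -= Lam[:, g, k]
            ll[ev[k], g] += loghaz_k[ev[k]] + zeta[g, k]

    theta = np.zeros(G)
    if G > 1:
        theta[1:] = x[struct.sl_theta]
    log_pi = theta - logsumexp(theta)
    num = ll + log_pi
    per_subject = logsumexp(num, axis=1)
    total = float(per_subject.sum())
    if not np.isfinite(total):
        return -np.inf, grad
    W = np.exp(num - per_subject[:, None])  # posterior weights (N, G)

    # ---- backward: longitudinal scores
    wv = np.repeat(W, data.n_i, axis=0)  # per-visit posterior weights
    grad_eta_acc = np.zeros(data.I.shape[1]) if struct.link_mode == "spline" \
        else None
    dll_dvb = 0.0
    dll_dve = 0.0
    for g in range(G):
        r, s = r_g[g], s_g[g]
        shrink = vb * s / denom
        e = (r - np.repeat(shrink, data.n_i)) / ve  # Sigma^{-1} r per visit
        we = wv[:, g] * e
        gb = np.empty(3)
        gb[0] = we.sum()
        gb[1] = we @ data.D[:, 1]
        gb[2] = we @ data.D[:, 2]
        # beta layout: rows (beta0, beta1, beta2) x G, flattened row-major
        b0 = struct.sl_beta.start
        grad[b0 + 0 * G + g] += gb[0]
        grad[b0 + 1 * G + g] += gb[1]
        grad[b0 + 2 * G + g] += gb[2]
        if gamma.size:
            grad[struct.sl_gamma] += data.Xl.T @ we
        if grad_eta_acc is not None:
            grad_eta_acc -= data.I.T @ we
        wg = W[:, g]
        dll_dvb += wg @ (-0.5 * (data.n_i / denom - (s / denom) ** 2))
        if struct.ix_lse is not None:
            rss = data.reduce(r * r)
            quad = (rss - vb * s * s / denom) / ve
            dve = -0.5 * ((data.n_i - 1) / ve + 1.0 / denom
                          + vb * s * s / (ve * denom**2) - quad / ve)
            dll_dve += wg @ dve
    grad[struct.ix_lsb] = dll_dvb * 2.0 * vb
    if struct.ix_lse is not None:
        grad[struct.ix_lse] = dll_dve * 2.0 * ve
    if grad_eta_acc is not None:
        # Jacobian part: class-independent since posterior weights sum to 1
        grad_eta_acc += data.M.T @ (1.0 / dh)
        grad[struct.sl_eta] = 2.0 * eta * grad_eta_acc

    # ---- backward: survival scores
    for k in range(2):
        wLam = (W * Lam[:, :, k]).sum(axis=1)  # posterior-averaged cumhaz
        evk = ev[k].astype(float)
        grad[struct.sl_lalpha.start + k] = float(
            (evk * (1.0 + alpha[k] * logT_c[k])).sum()
            - alpha[k] * (wLam @ logT_c[k])
        )
        grad[struct.sl_lsigma.start + k] = float(
            alpha[k] * (wLam.sum() - evk.sum())
        )
        if G > 1:
            zoff = struct.sl_zeta.start + k * (G - 1)
            for g in range(1, G):
                grad[zoff + g - 1] = float(
                    (W[:, g] * (evk - Lam[:, g, k])).sum()
                )
        if struct.p_surv:
            ooff = struct.sl_omega.start + k * struct.p_surv
            grad[ooff:ooff + struct.p_surv] = data.Xs.T @ (evk - wLam)

    if G > 1:
        pi = np.exp(log_pi)
        grad[struct.sl_theta] = W[:, 1:].sum(axis=0) - N * pi[1:]
    return total, grad


def joint_loglik(cohort: CohortData, params: ModelParams) -> float:
    """Observed-data log-likelihood of a cohort under given parameters.

    Computed with log-sum-exp stabilization over classes.  Raises if the
    likelihood is non-finite, naming the first offending subject.
    """
    link_mode = "spline" if params.link is not None else "identity"
    data = FitData(cohort, link_mode,
                   knots=None if params.link is None else params.link.knots)
    struct = _structure_for(data, params.G)
    x = struct.pack(params)
    ll, log_pi = _component_logliks(data, x, struct)
    per_subject = logsumexp(ll + log_pi, axis=1)
    bad = np.where(~np.isfinite(per_subject))[0]
    if len(bad):
        sid = data.subject_ids[bad[0]]
        raise ValueError(
            f"non-finite likelihood for subject {sid!r} "
            f"(classes {np.where(~np.isfinite(ll[bad[0]]))[0].tolist()})"
        )
    return float(per_subject.sum())


# ---------------------------------------------------------------------------
# fitting


def _initial_vector(data: FitData, struct: _Structure) -> np.ndarray:
    """Heuristic one-class start: moment-matched link scale, exponential
    survival rates from the crude event counts."""
    x = np.zeros(struct.n_params)
    sd_y = max(np.std(data.y), 0.5)
    if struct.link_mode == "spline":
        span = data.knots[-1] - data.knots[0]
        total = span / sd_y  # h range approximates the z-score range
        x[struct.sl_eta] = np.sqrt(total / struct.n_eta)
        eta2 = np.asarray(x[struct.sl_eta]) ** 2
        h = data.I @ eta2
    else:
        h = data.y
        x[struct.ix_lse] = np.log(sd_y * 0.7)
    beta = np.zeros((3, struct.G))
    beta[0, :] = h.mean()
    x[struct.sl_beta] = beta.ravel()
    x[struct.ix_lsb] = np.log(max(np.std(h) * 0.5, 1e-2))
    exposure = data.T.sum()
    for k in range(2):
        events = max(int((data.delta == k + 1).sum()), 1)
        rate = events / exposure
        x[struct.sl_lalpha.start + k] = 0.0
        x[struct.sl_lsigma.start + k] = -np.log(rate)
    return x


def _perturb(x1, struct1: _Structure, struct: _Structure, data: FitData,
             rng: np.random.Generator, scale: float) -> np.ndarray:
    """Expand a one-class solution to G classes with random jitter."""
    G = struct.G
    x = np.zeros(struct.n_params)
    if struct.link_mode == "spline":
        x[struct.sl_eta] = x1[struct1.sl_eta]
        eta2 = np.asarray(x1[struct1.sl_eta]) ** 2
        sd_h = max(np.std(data.I @ eta2), 0.3)
    else:
        x[struct.ix_lse] = x1[struct1.ix_lse]
        sd_h = max(np.std(data.y), 0.3)
    b1 = np.asarray(x1[struct1.sl_beta]).reshape(3, 1)
    beta = np.repeat(b1, G, axis=1)
    beta[0] += rng.normal(0.0, scale * sd_h, G)
    beta[1] += rng.normal(0.0, 0.15 * scale * sd_h, G)
    beta[2] += rng.normal(0.0, 0.15 * scale * sd_h, G)
    x[struct.sl_beta] = beta.ravel()
    x[struct.sl_gamma] = x1[struct1.sl_gamma]
    x[struct.ix_lsb] = x1[struct1.ix_lsb]
    x[struct.sl_lalpha] = x1[struct1.sl_lalpha]
    x[struct.sl_lsigma] = x1[struct1.sl_lsigma]
    x[struct.sl_zeta] = rng.normal(0.0, 0.7 * scale, 2 * (G - 1))
    x[struct.sl_omega] = x1[struct1.sl_omega]
    x[struct.sl_theta] = rng.normal(0.0, 0.3 * scale, G - 1)
    return x


def _subject_features(data: FitData, h):
    """Per-subject (mean before t=0, mean from t=0) of the transformed score,
    falling back to the subject's overall mean when one period is empty."""
    pre = data.t < 0
    overall = data.reduce(h) / data.n_i
    feats = np.empty((data.N, 2))
    for j, mask in enumerate((pre, ~pre)):
        s = data.reduce(np.where(mask, h, 0.0))
        c = data.reduce(mask.astype(float))
        feats[:, j] = np.where(c > 0, s / np.maximum(c, 1), overall)
    return feats


def _kmeans_start(x1, struct1, struct, data: FitData,
                  rng: np.random.Generator) -> np.ndarray:
    """Data-driven start: cluster subject trajectory summaries, then give
    each cluster its own piecewise least-squares line and crude event-rate
    log-hazard shift."""
    from scipy.cluster.vq import kmeans2

    G = struct.G
    x = np.zeros(struct.n_params)
    if struct.link_mode == "spline":
        x[struct.sl_eta] = x1[struct1.sl_eta]
        h = data.I @ np.asarray(x1[struct1.sl_eta]) ** 2
    else:
        x[struct.ix_lse] = x1[struct1.ix_lse]
        h = data.y
    feats = _subject_features(data, h)
    z = (feats - feats.mean(0)) / np.maximum(feats.std(0), 1e-8)
    _, lab = kmeans2(z, G, minit="++", seed=int(rng.integers(2**31)))
    # guard empty clusters
    for g in range(G):
        if not np.any(lab == g):
            lab[rng.integers(data.N)] = g
    beta = np.zeros((3, G))
    off = data.Xl @ np.asarray(x1[struct1.sl_gamma]) \
        if struct.p_long else 0.0
    vlab = np.repeat(lab, data.n_i)
    for g in range(G):
        m = vlab == g
        Dg = data.D[m]
        coef, *_ = np.linalg.lstsq(Dg, (h - off)[m] if struct.p_long
                                   else h[m], rcond=None)
        beta[:, g] = coef
    x[struct.sl_beta] = beta.ravel()
    x[struct.sl_gamma] = x1[struct1.sl_gamma]
    x[struct.ix_lsb] = x1[struct1.ix_lsb]
    x[struct.sl_lalpha] = x1[struct1.sl_lalpha]
    x[struct.sl_lsigma] = x1[struct1.sl_lsigma]
    x[struct.sl_omega] = x1[struct1.sl_omega]
    sizes = np.bincount(lab, minlength=G).astype(float)
    rates = np.empty((G, 2))
    exposure = np.array([data.T[lab == g].sum() for g in range(G)])
    for k in range(2):
        ev = np.array([float((data.delta[lab == g] == k + 1).sum())
                       for g in range(G)])
        rates[:, k] = (ev + 0.5) / np.maximum(exposure, 1e-8)
    lz = np.log(rates) - np.log(rates[0])
    x[struct.sl_zeta] = np.concatenate([lz[1:, 0], lz[1:, 1]])
    x[struct.sl_theta] = np.log(sizes[1:] / sizes[0])
    return x


def _split_start(x_prev, struct_prev, struct, data: FitData, split_class: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Warm start for G classes from a (G-1)-class solution: duplicate one
    class with jittered level, halving its prior weight.  Guarantees the
    enumeration's maximized likelihood is (numerically) nondecreasing in G."""
    Gp = struct_prev.G
    x = np.zeros(struct.n_params)
    if struct.link_mode == "spline":
        x[struct.sl_eta] = x_prev[struct_prev.sl_eta]
        sd_h = max(np.std(data.I @ np.asarray(
            x_prev[struct_prev.sl_eta]) ** 2), 0.3)
    else:
        x[struct.ix_lse] = x_prev[struct_prev.ix_lse]
        sd_h = max(np.std(data.y), 0.3)
    beta_p = np.asarray(x_prev[struct_prev.sl_beta]).reshape(3, Gp)
    new = beta_p[:, split_class].copy()
    new[0] += rng.normal(0.0, 0.4 * sd_h)
    beta = np.column_stack([beta_p, new])
    x[struct.sl_beta] = beta.ravel()
    x[struct.sl_gamma] = x_prev[struct_prev.sl_gamma]
    x[struct.ix_lsb] = x_prev[struct_prev.ix_lsb]
    x[struct.sl_lalpha] = x_prev[struct_prev.sl_lalpha]
    x[struct.sl_lsigma] = x_prev[struct_prev.sl_lsigma]
    x[struct.sl_omega] = x_prev[struct_prev.sl_omega]
    zeta_p = np.zeros((Gp, 2))
    theta_p = np.zeros(Gp)
    if Gp > 1:
        zp = np.asarray(x_prev[struct_prev.sl_zeta]).reshape(2, Gp - 1)
        zeta_p[1:, 0], zeta_p[1:, 1] = zp[0], zp[1]
        theta_p[1:] = x_prev[struct_prev.sl_theta]
    zeta = np.vstack([zeta_p, zeta_p[split_class]])
    theta = np.concatenate([theta_p, [theta_p[split_class] - np.log(2.0)]])
    theta[split_class] -= np.log(2.0)
    x[struct.sl_zeta] = np.concatenate([zeta[1:, 0], zeta[1:, 1]])
    x[struct.sl_theta] = theta[1:] - theta[0]
    return x


def _minimize(data, struct, x0, maxiter, ftol, gtol):
    def nll(x):
        v, g = _value_and_grad(data, x, struct)
        if not np.isfinite(v):
            return _BIG, np.zeros_like(x)
        return -v, -g

    return minimize(nll, x0, jac=True, method="L-BFGS-B",
                    options={"maxiter": maxiter, "ftol": ftol, "gtol": gtol,
                             "maxcor": 20, "maxfun": 10 * (maxiter + 10)})


def _relabel(x, struct: _Structure, data: FitData) -> np.ndarray:
    """Deterministic class order: ascending back-transformed score at t = 0;
    ties broken by descending class size.  Reference constraints (zeta and
    theta of the new first class = 0) are restored by absorbing the shift
    into the Weibull scales, which leaves the likelihood unchanged."""
    G = struct.G
    if G == 1:
        return x
    params = struct.unpack(x, data.knots)
    beta0 = np.array([c.beta0 for c in params.classes])
    if params.link is not None:
        key = np.array([invert_link(b, params.link) for b in beta0])
    else:
        key = beta0
    pi = class_prior(params.membership)
    order = sorted(range(G), key=lambda g: (round(key[g], 10), -pi[g]))
    beta = np.asarray(x[struct.sl_beta]).reshape(3, G)[:, order]
    zeta = np.zeros((G, 2))
    z = np.asarray(x[struct.sl_zeta]).reshape(2, G - 1)
    zeta[1:, 0], zeta[1:, 1] = z[0], z[1]
    zeta = zeta[order]
    theta = np.zeros(G)
    theta[1:] = x[struct.sl_theta]
    theta = theta[order]
    x = x.copy()
    x[struct.sl_beta] = beta.ravel()
    shift = zeta[0].copy()
    zeta = zeta - shift  # new reference row becomes 0
    # keep every hazard invariant: Lambda = (T/s)^a * exp(zeta), so dropping
    # c from zeta requires s -> s * exp(-c/a)
    alpha = np.exp(np.asarray(x[struct.sl_lalpha]))
    x[struct.sl_lsigma] = np.asarray(x[struct.sl_lsigma]) - shift / alpha
    x[struct.sl_zeta] = np.concatenate([zeta[1:, 0], zeta[1:, 1]])
    x[struct.sl_theta] = theta[1:] - theta[0]
    return x


def _posterior_from_x(data: FitData, x, struct: _Structure):
    ll, log_pi = _component_logliks(data, x, struct)
    num = ll + log_pi
    post = softmax(num, axis=1)
    return post


def fit_jlcmm(cohort: CohortData, G: int, config: FitConfig | None = None,
              _data: FitData | None = None,
              _one_class: np.ndarray | None = None,
              _warm=None) -> FittedModel:
    """Fit the G-class joint model by seeded multi-start quasi-Newton.

    The one-class model is fit first from a deterministic heuristic start.
    For G > 1, candidate starts are (a) a data-driven start that clusters
    per-subject trajectory summaries, (b) ``config.n_starts`` randomly
    perturbed replications of the one-class solution, and (c) when called
    from the enumeration, class-split warm starts from the previous
    solution.  All candidates get a short run; the best is continued to
    full convergence.  Classes in the returned model are relabeled so class
    1 has the lowest model-implied score at the centering time.
    """
    if G < 1:
        raise ValueError("G must be >= 1")
    config = config or FitConfig()
    data = _data if _data is not None else build_fit_data(cohort, config)
    rng = np.random.default_rng(config.seed)
    struct1 = _structure_for(data, 1)
    if _one_class is None:
        res1 = _minimize(data, struct1, _initial_vector(data, struct1),
                         config.max_iters, config.ftol, config.gtol)
        x1 = res1.x
    else:
        x1 = _one_class
    if G == 1:
        res = _minimize(data, struct1, x1, config.max_iters, config.ftol,
                        config.gtol)
        best_x, struct = res.x, struct1
        traces = [(-res.fun, res.nit)]
        success = bool(res.success or res.status == 1)
    else:
        struct = _structure_for(data, G)
        starts = [_kmeans_start(x1, struct1, struct, data, rng)]
        for s in range(config.n_starts):
            starts.append(_perturb(x1, struct1, struct, data, rng,
                                   config.perturb_scale))
        if _warm is not None:
            x_prev, struct_prev = _warm
            for c in range(struct_prev.G):
                starts.append(_split_start(x_prev, struct_prev, struct,
                                           data, c, rng))
        traces = []
        cand = []
        for x0 in starts:
            r = _minimize(data, struct, x0, config.short_run_iters,
                          config.ftol, config.gtol)
            cand.append(r.x)
            traces.append((-r.fun, r.nit))
        best = int(np.argmax([t[0] for t in traces]))
        res = _minimize(data, struct, cand[best], config.max_iters,
                        config.ftol, config.gtol)
        best_x = res.x
        success = bool(res.success or res.status == 1)
        traces.append((-res.fun, res.nit))
    if not np.isfinite(res.fun) or res.fun >= _BIG:
        raise RuntimeError(
            f"no start reached a finite optimum for G={G}; "
            f"per-start logliks: {[t[0] for t in traces]}"
        )
    best_x = _relabel(best_x, struct, data)
    loglik = _loglik_vec(data, best_x, struct)
    post = _posterior_from_x(data, best_x, struct)
    params = struct.unpack(best_x, data.knots)
    n_params = struct.n_params
    bic = -2.0 * loglik + n_params * np.log(data.N)
    return FittedModel(
        params=params,
        loglik=loglik,
        n_params=n_params,
        bic=bic,
        posterior=post,
        modal_class=post.argmax(axis=1),
        subject_ids=data.subject_ids,
        convergence={"success": success, "status": int(res.status),
                     "message": str(res.message), "n_iter": int(res.nit),
                     "starts": traces},
        config=config,
        _data=data,
    )


def posterior_class_probs(fitted: FittedModel,
                          cohort: CohortData | None = None) -> np.ndarray:
    """Bayes-rule posterior class probabilities, one row per subject.

    With ``cohort`` given, posteriors are computed fresh for that cohort
    under the fitted parameters; otherwise the fit's own cohort is used.
    """
    params = fitted.params
    if cohort is None:
        data = fitted._data
    else:
        mode = "spline" if params.link is not None else "identity"
        data = FitData(cohort, mode,
                       knots=None if params.link is None
                       else params.link.knots)
    struct = _structure_for(data, params.G)
    return _posterior_from_x(data, struct.pack(params), struct)


def enumerate_classes(cohort: CohortData, G_max: int,
                      config: FitConfig | None = None):
    """Fit G = 1..G_max and select the class count by minimum BIC.

    Returns ``(table, best_model)`` where the table has one row per G with
    log-likelihood, parameter count, BIC, the smallest modal-class share and
    the mean highest posterior probability.  A G whose fit fails is recorded
    as a failed row and skipped by the selection.
    """
    if G_max < 1:
        raise ValueError("G_max must be >= 1")
    config = config or FitConfig()
    data = build_fit_data(cohort, config)
    struct1 = _structure_for(data, 1)
    res1 = _minimize(data, struct1, _initial_vector(data, struct1),
                     config.max_iters, config.ftol, config.gtol)
    rows, models = [], {}
    warm = None
    for G in range(1, G_max + 1):
        try:
            m = fit_jlcmm(cohort, G, config, _data=data, _one_class=res1.x,
                          _warm=warm)
            warm = (_structure_for(data, G).pack(m.params),
                    _structure_for(data, G))
        except Exception as exc:  # recorded, selection proceeds
            logger.warning("fit failed for G=%d: %s", G, exc)
            rows.append({"G": G, "loglik": np.nan, "n_params": np.nan,
                         "bic": np.nan, "min_class_share": np.nan,
                         "mean_max_posterior": np.nan, "converged": False})
            continue
        shares = np.bincount(m.modal_class, minlength=G) / data.N
        rows.append({
            "G": G, "loglik": m.loglik, "n_params": m.n_params,
            "bic": m.bic, "min_class_share": float(shares.min()),
            "mean_max_posterior": float(m.posterior.max(axis=1).mean()),
            "converged": bool(m.convergence["success"]),
        })
        models[G] = m
    table = pd.DataFrame(rows)
    if not models:
        raise RuntimeError("all class counts failed to fit")
    ok = table.dropna(subset=["bic"])
    best_G = int(ok.loc[ok["bic"].idxmin(), "G"])
    table["selected"] = table["G"] == best_G
    return table, models[best_G]


# ---------------------------------------------------------------------------
# uncertainty


def observed_information(fitted: FittedModel) -> np.ndarray:
    """Observed information (negative Hessian of the log-likelihood) at the
    optimum, by central finite differences on the packed parameters."""
    data = fitted._data
    struct = _structure_for(data, fitted.G)
    x = struct.pack(fitted.params)
    n = len(x)
    eps = 1e-4 * (1.0 + np.abs(x))

    def f(v):
        return -_loglik_vec(data, v, struct)

    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps[i]
            ej = np.zeros(n); ej[j] = eps[j]
            val = (f(x + ei + ej) - f(x + ei - ej)
                   - f(x - ei + ej) + f(x - ei - ej)) / (4 * eps[i] * eps[j])
            H[i, j] = H[j, i] = val
    return H


def class_hazard_ratios(fitted: FittedModel, ref_class: int = 0,
                        information: np.ndarray | None = None) -> pd.DataFrame:
    """Per-class hazard ratios vs the reference with Wald 95% CIs.

    Standard errors come from the inverse observed information (finite-
    difference Hessian at the optimum); if that matrix is singular the CIs
    are flagged unavailable.  ``ref_class`` other than the fitted reference
    re-expresses the ratios against the chosen class.
    """
    if fitted.G < 2:
        raise ValueError("hazard ratios need at least two classes")
    data = fitted._data
    struct = _structure_for(data, fitted.G)
    if information is None:
        information = observed_information(fitted)
    cov = None
    try:
        cov = np.linalg.inv(information)
        if np.any(np.diag(cov) < 0):
            cov = None
    except np.linalg.LinAlgError:
        pass
    zeta = fitted.params.survival.zeta
    rows = []
    zoff = struct.sl_zeta.start
    G = fitted.G
    for k, cause in enumerate(("dementia", "death")):
        for g in range(G):
            if g == ref_class:
                continue
            lz = zeta[g, k] - zeta[ref_class, k]
            se = np.nan
            if cov is not None:
                # packed zeta entries exist for classes 1..G-1
                def _ix(cls):
                    return zoff + k * (G - 1) + (cls - 1)
                if ref_class == 0:
                    var = cov[_ix(g), _ix(g)] if g >= 1 else np.nan
                else:
                    a, b = _ix(g) if g >= 1 else None, _ix(ref_class)
                    if g == 0:
                        var = cov[b, b]
                    else:
                        var = cov[a, a] + cov[b, b] - 2 * cov[a, b]
                se = float(np.sqrt(var)) if var >= 0 else np.nan
            lo, hi = (np.exp(lz - 1.96 * se), np.exp(lz + 1.96 * se)) \
                if np.isfinite(se) else (np.nan, np.nan)
            rows.append({"cause": cause, "class": g, "log_hr": lz,
                         "hr": float(np.exp(lz)), "se": se,
                         "ci_lo": lo, "ci_hi": hi,
                         "ci_available": bool(np.isfinite(se))})
    return pd.DataFrame(rows)
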