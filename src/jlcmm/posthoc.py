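"""Posterior-weighted multinomial regression and group comparison tables.

After classification, two downstream analyses link latent class membership
to external variables:

* **Weighted multinomial logistic regression** of class membership on MRI
  burden (WM-SVID, AD-PS), each standardised to per-SD units.  Membership
  is uncertain, so each subject's row is weighted by the posterior
  probability of her modal class; the weighted log-likelihood
  ``sum_i w_i log P(class_i | x_i)`` is maximised by Newton iterations with
  Wald inference from the weighted information matrix.
* **Baseline characteristic comparisons** across classes: one-way ANOVA
  F-tests for continuous variables, chi-squared (or Fisher exact for sparse
  2x2 tables) for categorical ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ClassAssociationResult",
    "weighted_multinomial_fit",
    "standardize_exposure",
    "baseline_comparison",
]

_SEPARATION_BOUND = 15.0  # |coef| beyond this on standardised scale


@dataclass
class ClassAssociationResult:
    """Per-class odds ratios from one weighted multinomial fit."""

    table: pd.DataFrame  # columns: class, term, coef, se, or_, ci_lo, ci_hi, p
    coef: np.ndarray  # (C-1, p) raw coefficients, non-reference classes
    cov: np.ndarray  # covariance of vec(coef)
    loglik: float
    n: int
    classes: np.ndarray
    ref_class: object
    converged: bool
    separation: bool
    meta: dict = field(default_factory=dict)


def standardize_exposure(values):
    """Center and scale to per-SD units on complete cases.

    Returns ``(z, mean, sd)``; ``z`` has NaN where the input was missing
    (those rows are excluded downstream, with a logged count).  SD uses the
    n-1 denominator.
    """
    v = np.asarray(values, dtype=float)
    ok = np.isfinite(v)
    n_miss = int((~ok).sum())
    if n_miss:
        logger.info("standardize_exposure: %d missing values excluded", n_miss)
    if ok.sum() < 2:
        raise ValueError("need at least 2 non-missing values")
    mean = float(v[ok].mean())
    sd = float(v[ok].std(ddof=1))
    if sd == 0:
        raise ValueError("zero standard deviation")
    z = np.full_like(v, np.nan)
    z[ok] = (v[ok] - mean) / sd
    return z, mean, sd


def _multinomial_newton(X, Y, w, max_iter=100, tol=1e-10):
    """Newton-Raphson for the weighted multinomial log-likelihood.

    ``Y`` is an (n, C) indicator matrix with the reference class in column
    0; coefficients are estimated for columns 1..C-1.  Returns
    ``(B, cov, loglik, converged)``.
    """
    n, p = X.shape
    C = Y.shape[1]
    K = (C - 1) * p
    B = np.zeros((C - 1, p))
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = X @ B.T  # (n, C-1)
        m = np.maximum(eta.max(axis=1), 0.0)
        Z = np.exp(-m) + np.exp(eta - m[:, None]).sum(axis=1)
        logZ = m + np.log(Z)
        P = np.exp(eta - logZ[:, None])  # P(class c>=1)
        ll = float((w * ((Y[:, 1:] * eta).sum(axis=1) - logZ)).sum())
        grad = ((w[:, None] * (Y[:, 1:] - P)).T @ X).ravel()
        H = np.empty((K, K))
        for a in range(C - 1):
            for b_ in range(a, C - 1):
                d = P[:, a] * ((a == b_) - P[:, b_])
                blk = -(X * (w * d)[:, None]).T @ X
                H[a * p:(a + 1) * p, b_ * p:(b_ + 1) * p] = blk
                H[b_ * p:(b_ + 1) * p, a * p:(a + 1) * p] = blk.T
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # Newton direction with step halving on the weighted log-likelihood
        lam = 1.0
        for _ in range(30):
            Bn = B - lam * step.reshape(C - 1, p)
            eta_n = X @ Bn.T
            mn = np.maximum(eta_n.max(axis=1), 0.0)
            logZn = mn + np.log(np.exp(-mn)
                                + np.exp(eta_n - mn[:, None]).sum(axis=1))
            ll_n = float((w * ((Y[:, 1:] * eta_n).sum(axis=1) - logZn)).sum())
            if ll_n >= ll - 1e-12:
                break
            lam *= 0.5
        B = Bn
        if abs(ll_n - ll_old) < tol * (1.0 + abs(ll_n)):
            converged = True
            ll = ll_n
            break
        ll_old = ll_n
        ll = ll_n
    cov = np.linalg.pinv(-H)
    return B, cov, ll, converged


def weighted_multinomial_fit(outcome_class, weights, exposures,
                             covariates=None, ref_class=None,
                             exposure_names=None) -> ClassAssociationResult:
    """Weighted multinomial logistic regression of class on exposures.

    ``exposures`` (array or DataFrame, columns standardised to per-SD units
    beforehand or here if raw) enter alongside optional ``covariates``; an
    intercept is always included.  ``weights`` are the posterior
    probabilities of each subject's modal class (in (0, 1]).  Rows with any
    missing value are dropped with a logged count.  Classes with no
    observations are dropped with a warning; apparent separation (a
    coefficient running away) is flagged in the result.
    """
    y = np.asarray(outcome_class)
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0) or np.any(w > 1 + 1e-12):
        raise ValueError("weights must lie in (0, 1]")
    if isinstance(exposures, pd.DataFrame):
        exposure_names = exposure_names or list(exposures.columns)
        E = exposures.to_numpy(dtype=float)
    else:
        E = np.atleast_2d(np.asarray(exposures, dtype=float))
        if E.shape[0] == 1 and len(y) != 1:
            E = E.T
        exposure_names = exposure_names or [
            f"exposure_{j}" for j in range(E.shape[1])]
    parts = [E]
    cov_names = []
    if covariates is not None:
        Cv = covariates.to_numpy(dtype=float) if isinstance(
            covariates, pd.DataFrame) else np.asarray(covariates, dtype=float)
        if Cv.ndim == 1:
            Cv = Cv[:, None]
        cov_names = (list(covariates.columns)
                     if isinstance(covariates, pd.DataFrame)
                     else [f"cov_{j}" for j in range(Cv.shape[1])])
        parts.append(Cv)
    Xraw = np.column_stack(parts)
    ok = np.all(np.isfinite(Xraw), axis=1) & np.isfinite(w)
    n_drop = int((~ok).sum())
    if n_drop:
        logger.info("weighted_multinomial_fit: dropping %d incomplete rows",
                    n_drop)
    y, w, Xraw = y[ok], w[ok], Xraw[ok]

    levels = pd.unique(y)
    if ref_class is None:
        ref_class = sorted(levels)[0]
    observed = [ref_class] + sorted(set(levels) - {ref_class})
    if len(observed) < 2:
        raise ValueError("outcome must have at least 2 observed classes")
    Y = np.column_stack([(y == c).astype(float) for c in observed])
    empty = Y.sum(axis=0) == 0
    if empty.any():
        dropped = [c for c, e in zip(observed, empty) if e]
        logger.warning("dropping empty classes %s", dropped)
        observed = [c for c, e in zip(observed, empty) if not e]
        Y = Y[:, ~empty]
    X = np.column_stack([np.ones(len(y)), Xraw])
    names = ["intercept"] + exposure_names + cov_names
    B, cov, ll, converged = _multinomial_newton(X, Y, w)
    separation = bool(np.any(np.abs(B) > _SEPARATION_BOUND))
    if separation:
        logger.warning("possible separation: coefficient(s) unbounded")
    se = np.sqrt(np.maximum(np.diag(cov), 0.0)).reshape(B.shape)
    rows = []
    for c in range(B.shape[0]):
        for j, nm in enumerate(names):
            coef = B[c, j]
            z = coef / se[c, j] if se[c, j] > 0 else np.nan
            rows.append({
                "class": observed[c + 1], "term": nm, "coef": coef,
                "se": se[c, j], "or_": float(np.exp(coef)),
                "ci_lo": float(np.exp(coef - 1.96 * se[c, j])),
                "ci_hi": float(np.exp(coef + 1.96 * se[c, j])),
                "p": float(2 * stats.norm.sf(abs(z))) if np.isfinite(z)
                else np.nan,
            })
    return ClassAssociationResult(
        table=pd.DataFrame(rows), coef=B, cov=cov, loglik=ll, n=len(y),
        classes=np.asarray(observed, dtype=object), ref_class=ref_class,
        converged=converged, separation=separation,
        meta={"exposures": exposure_names, "covariates": cov_names,
              "weighted": bool(np.any(w < 1.0))},
    )


def baseline_comparison(table: pd.DataFrame, group: str, variable: str,
                        kind: str):
    """Test a baseline characteristic across latent classes.

    ``kind='continuous'`` runs a one-way ANOVA F-test; ``kind='categorical'``
    a Pearson chi-squared test on the contingency table, switching to the
    Fisher exact test for 2x2 tables with any expected count below 5.
    Missing categorical values are kept as an explicit "missing" level.
    Returns ``(statistic, p_value, method)``.
    """
    g = table[group]
    if g.nunique() < 2:
        raise ValueError("need at least two groups")
    if kind == "continuous":
        samples = [v.dropna().to_numpy()
                   for _, v in table.groupby(group)[variable]]
        stat, p = stats.f_oneway(*samples)
        return float(stat), float(p), "anova"
    if kind != "categorical":
        raise ValueError("kind must be 'continuous' or 'categorical'")
    v = table[variable].astype(object).where(table[variable].notna(),
                                             "missing")
    ct = pd.crosstab(v, g).to_numpy()
    chi2, p, dof, expected = stats.chi2_contingency(ct, correction=False)
    if ct.shape == (2, 2) and (expected < 5).any():
        odds, p = stats.fisher_exact(ct)
        return float(odds), float(p), "fisher"
    return float(chi2), float(p), "chi2"
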