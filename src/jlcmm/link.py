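"""Monotone spline link for bounded, skewed symptom scores.

The 15-item Geriatric Depression Scale (GDS-15) is an integer score on
[0, 15] with a strong floor: most community-dwelling respondents score 0-2.
A Gaussian mixed model on the raw score is therefore misspecified.  Instead
the model works on a transformed scale ``h = H(y; eta)`` where ``H`` is a
monotone quantile-knot I-spline curve estimated jointly with the rest of the
model.  Monotonicity is guaranteed structurally: each basis coefficient
enters as its square, so ``H' = sum_k eta_k^2 M_k(y) >= 0`` everywhere.

The basis is quadratic: M-splines ``M_k`` (densities, integrating to one)
and their integrals, the I-splines ``I_k`` (each rising from 0 at the first
knot to 1 at the last).  With ``K`` knots there are ``K + 1`` basis
functions plus the offset ``eta0``.  One location and one scale
normalisation are required to separate the link from the trajectory model:
here ``eta0`` is fixed to 0 and the residual SD of the transformed outcome
is fixed to 1, leaving the class intercepts free and interpretable on the
transformed scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "LinkParams",
    "LinkBasis",
    "fit_link_knots",
    "evaluate_link",
    "invert_link",
    "identity_coefficients",
    "n_link_coefficients",
]

_DEGREE = 2  # quadratic M-splines


def n_link_coefficients(knots) -> int:
    """Number of squared basis coefficients for a given knot vector."""
    return len(knots) + _DEGREE - 1


@dataclass
class LinkParams:
    """Parameters of the monotone spline transformation ``H``.

    ``eta`` holds the *unconstrained* coefficients; they enter the curve as
    ``eta_k ** 2``.  ``eta0`` is the offset (fixed at 0 during joint
    estimation; kept as a field so alternative normalisations remain
    expressible).
    """

    knots: np.ndarray
    eta0: float = 0.0
    eta: np.ndarray = field(default=None)

    def __post_init__(self):
        self.knots = np.asarray(self.knots, dtype=float)
        if self.knots.ndim != 1 or len(self.knots) < 2:
            raise ValueError("need at least two knots")
        if np.any(np.diff(self.knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        if self.eta is None:
            self.eta = np.ones(n_link_coefficients(self.knots))
        self.eta = np.asarray(self.eta, dtype=float)
        if len(self.eta) != n_link_coefficients(self.knots):
            raise ValueError(
                f"expected {n_link_coefficients(self.knots)} coefficients, "
                f"got {len(self.eta)}"
            )


class LinkBasis:
    """Precomputed I-spline / M-spline basis on a fixed knot vector.

    Building the per-basis ``BSpline`` objects once and reusing them makes
    repeated likelihood evaluations (where only ``eta`` moves) cheap: the
    transformation is linear in ``eta**2`` given the basis matrices.
    """

    def __init__(self, knots):
        knots = np.asarray(knots, dtype=float)
        if np.any(np.diff(knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        self.knots = knots
        k = _DEGREE
        # clamped knot vector: boundary knots repeated degree+1 times
        t = np.concatenate([[knots[0]] * k, knots, [knots[-1]] * k])
        self._t = t
        self.n_basis = len(t) - k - 1
        order = k + 1
        self._msplines = []
        self._isplines = []
        for i in range(self.n_basis):
            c = np.zeros(self.n_basis)
            c[i] = 1.0
            b = BSpline(t, c, k, extrapolate=False)
            span = t[i + order] - t[i]
            # M-spline: B-spline scaled to integrate to one
            scale = order / span
            self._msplines.append((b, scale))
            # I-spline: running integral of the M-spline, reaches 1 at the
            # last knot
            self._isplines.append((b.antiderivative(), scale))

    def _check_domain(self, y):
        y = np.asarray(y, dtype=float)
        lo, hi = self.knots[0], self.knots[-1]
        if np.any(y < lo - 1e-12) or np.any(y > hi + 1e-12):
            raise ValueError(
                f"score outside link domain [{lo}, {hi}]: "
                f"range seen [{y.min()}, {y.max()}]"
            )
        return np.clip(y, lo, hi)

    def design(self, y):
        """Return ``(I, M)`` basis matrices, each ``(len(y), n_basis)``."""
        y = np.atleast_1d(self._check_domain(y))
        hi = self.knots[-1]
        # evaluate M just inside the right boundary so the clamped B-spline
        # limit is used instead of the out-of-domain NaN
        y_m = np.minimum(y, hi - 1e-9 * max(1.0, abs(hi)))
        I = np.empty((len(y), self.n_basis))
        M = np.empty((len(y), self.n_basis))
        for j, ((ib, iscale), (mb, mscale)) in enumerate(
            zip(self._isplines, self._msplines)
        ):
            I[:, j] = ib(y) * iscale
            M[:, j] = mb(y_m) * mscale
        np.nan_to_num(I, copy=False)
        np.nan_to_num(M, copy=False)
        return I, M

    def transform(self, y, params: LinkParams):
        """Evaluate ``(H(y), H'(y))`` for given coefficients."""
        I, M = self.design(y)
        eta2 = params.eta**2
        return params.eta0 + I @ eta2, M @ eta2


def fit_link_knots(scores, n_knots: int = 3) -> np.ndarray:
    """Place knots at empirical quantiles of the observed scores.

    The first and last knots sit at the observed min and max; interior knots
    at the evenly spaced quantiles between them.  Coincident knots (heavily
    tied score distributions) are nudged apart by a fixed epsilon.
    """
    scores = np.asarray(scores, dtype=float)
    scores = scores[np.isfinite(scores)]
    if n_knots < 2:
        raise ValueError("need at least 2 knots")
    if scores.size == 0 or np.ptp(scores) == 0:
        raise ValueError("degenerate score distribution: all values identical")
    qs = np.linspace(0, 1, n_knots)
    knots = np.quantile(scores, qs)
    knots[0], knots[-1] = scores.min(), scores.max()
    eps = 1e-3 * max(np.ptp(scores), 1.0)
    for i in range(1, len(knots)):
        if knots[i] <= knots[i - 1]:
            knots[i] = knots[i - 1] + eps
    if knots[-1] > scores.max():
        # nudging pushed interior knots past the boundary; respace
        knots = np.linspace(scores.min(), scores.max(), n_knots)
    return knots


def identity_coefficients(knots) -> LinkParams:
    """Coefficients making the spline exactly linear: ``H(y) = y - knots[0]``.

    Each I-spline's density integrates to one, so weighting coefficient k by
    the knot span of basis k divided by the spline order makes the densities
    sum to the constant 1.  Used to verify that the transformed model
    degenerates to an untransformed linear mixed model.
    """
    knots = np.asarray(knots, dtype=float)
    k = _DEGREE
    t = np.concatenate([[knots[0]] * k, knots, [knots[-1]] * k])
    order = k + 1
    n = len(t) - order
    eta = np.sqrt([(t[i + order] - t[i]) / order for i in range(n)])
    return LinkParams(knots, 0.0, eta)


def evaluate_link(y, params: LinkParams):
    """Evaluate the transformation and its derivative at scores ``y``."""
    return LinkBasis(params.knots).transform(y, params)


def invert_link(h, params: LinkParams, tol: float = 1e-10):
    """Invert ``H`` by monotone bisection; clips out-of-range values.

    Values of ``h`` below ``H(min)`` or above ``H(max)`` are mapped to the
    respective boundary score with a warning (the curve is only defined on
    the observed score range).
    """
    basis = LinkBasis(params.knots)
    scalar = np.ndim(h) == 0
    h = np.atleast_1d(np.asarray(h, dtype=float))
    lo, hi = params.knots[0], params.knots[-1]
    h_lo, _ = basis.transform(np.array([lo]), params)
    h_hi, _ = basis.transform(np.array([hi]), params)
    h_lo, h_hi = h_lo[0], h_hi[0]
    if np.any(h < h_lo - 1e-9) or np.any(h > h_hi + 1e-9):
        warnings.warn(
            "values outside the range of the link; clipped to score bounds",
            stacklevel=2,
        )
    hc = np.clip(h, h_lo, h_hi)
    a = np.full(h.shape, lo)
    b = np.full(h.shape, hi)
    for _ in range(64):
        mid = 0.5 * (a + b)
        hm, _ = basis.transform(mid, params)
        left = hm < hc
        a = np.where(left, mid, a)
        b = np.where(left, b, mid)
        if np.max(b - a) < tol:
            break
    y = 0.5 * (a + b)
    return float(y[0]) if scalar else y
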