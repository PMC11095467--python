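"""Latent-class membership prior (intercept-only multinomial logit)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import softmax

__all__ = ["MembershipParams", "class_prior", "logits_from_proportions"]


@dataclass
class MembershipParams:
    """Class logits ``theta_g`` with the reference (first) class fixed at 0."""

    theta: np.ndarray

    def __post_init__(self):
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        if self.theta[0] != 0.0:
            raise ValueError("reference-class logit must be 0")

    @property
    def n_classes(self) -> int:
        return self.theta.size


def class_prior(params: MembershipParams) -> np.ndarray:
    """Prior class probabilities: softmax of the logits."""
    return softmax(params.theta)


def logits_from_proportions(pi) -> MembershipParams:
    """Invert the softmax: logits reproducing given proportions exactly."""
    pi = np.asarray(pi, dtype=float)
    if np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError("proportions must be positive and sum to 1")
    theta = np.log(pi) - np.log(pi[0])
    return MembershipParams(theta)
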