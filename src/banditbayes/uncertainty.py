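"""The three uncertainty levels computed from a belief state.

- *Risk*: irreducible outcome uncertainty — Shannon entropy (nats) of the
  posterior-mean outcome probabilities; maximal (ln 3) at the uniform
  triplet.
- *Estimation uncertainty* (ambiguity): spread of the posterior over the
  probability simplex — either the summed component variances of the
  Dirichlet or its differential entropy (which may be negative).
- *Unexpected uncertainty*: the probability that the outcome probabilities
  have jumped, 1 - pi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, psi, xlogy

__all__ = [
    "UncertaintyReport",
    "risk_entropy",
    "dirichlet_variance",
    "dirichlet_entropy",
    "estimation_uncertainty_variance",
    "estimation_uncertainty_entropy",
    "unexpected_uncertainty",
    "uncertainty_report",
]


def risk_entropy(mean_probs) -> float:
    """Shannon entropy -sum p ln p in nats, with 0 ln 0 = 0."""
    p = np.asarray(mean_probs, dtype=float)
    return float(-np.sum(xlogy(p, p)))


def dirichlet_variance(alpha, aggregate: str = "sum") -> np.ndarray | float:
    """Scalarised component variances of Dirichlet(alpha).

    Var[p_i] = alpha_i (alpha_0 - alpha_i) / (alpha_0^2 (alpha_0 + 1)),
    aggregated over components by summation (default) or by mean.
    Accepts a trailing-axis batch of parameter vectors.
    """
    alpha = np.asarray(alpha, dtype=float)
    a0 = alpha.sum(axis=-1, keepdims=True)
    var = alpha * (a0 - alpha) / (a0**2 * (a0 + 1.0))
    if aggregate == "sum":
        out = var.sum(axis=-1)
    elif aggregate == "mean":
        out = var.mean(axis=-1)
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    return float(out) if np.ndim(out) == 0 else out


def dirichlet_entropy(alpha, negate: bool = False) -> np.ndarray | float:
    """Differential entropy of Dirichlet(alpha) in nats.

    H = ln B(alpha) + (alpha_0 - K) psi(alpha_0) - sum_i (alpha_i - 1) psi(alpha_i)

    The flat Dirichlet(1,1,1) gives -ln 2 (a density of 2 on a region of
    area 1/2); concentration drives H to -inf. ``negate`` flips the sign
    for a precision-style reading.
    """
    alpha = np.asarray(alpha, dtype=float)
    a0 = alpha.sum(axis=-1)
    k = alpha.shape[-1]
    log_b = gammaln(alpha).sum(axis=-1) - gammaln(a0)
    ent = log_b + (a0 - k) * psi(a0) - ((alpha - 1.0) * psi(alpha)).sum(axis=-1)
    if negate:
        ent = -ent
    return float(ent) if np.ndim(ent) == 0 else ent


def estimation_uncertainty_variance(belief, aggregate: str = "sum") -> float:
    """Variance metric of a belief's posterior Dirichlet."""
    return float(dirichlet_variance(belief.alpha, aggregate=aggregate))


def estimation_uncertainty_entropy(belief, negate: bool = False) -> float:
    """Entropy metric (differential entropy) of a belief's posterior."""
    return float(dirichlet_entropy(belief.alpha, negate=negate))


def unexpected_uncertainty(pi: float) -> float:
    """Unexpected uncertainty 1 - pi, the inferred jump probability."""
    if not 0.0 < pi < 1.0:
        raise ValueError("pi must lie in (0, 1)")
    return 1.0 - pi


@dataclass(frozen=True)
class UncertaintyReport:
    """All three uncertainty levels for one arm at one trial."""

    risk: float  #: entropy of the posterior-mean probabilities, <= ln 3
    estimation_variance: float  #: summed Dirichlet component variances
    estimation_entropy: float  #: Dirichlet differential entropy (may be < 0)
    unexpected: float  #: 1 - pi


def uncertainty_report(belief, pi: float) -> UncertaintyReport:
    from .bayes import posterior_mean

    return UncertaintyReport(
        risk=risk_entropy(posterior_mean(belief)),
        estimation_variance=estimation_uncertainty_variance(belief),
        estimation_entropy=estimation_uncertainty_entropy(belief),
        unexpected=unexpected_uncertainty(pi),
    )
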