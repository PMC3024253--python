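"""Forgetting-Bayesian Dirichlet learner with explicit learning rates.

Each arm's outcome probabilities are learned under a Dirichlet belief whose
posterior parameters are summarised by a prior centre ``c0`` with precision
``nu0``, an effective data count ``n`` and a sufficient statistic ``z``
(running weighted outcome frequencies), so that

    alpha = nu0 * c0 + n * z,
    posterior mean = (nu0 * c0 + n * z) / (nu0 + n).

Because outcome probabilities may jump to fresh values, standard conjugate
updating is stabilised by *forgetting*: after each observation the belief is
mixed with the reset prior, weighted by the posterior probability ``pi``
that no jump occurred this trial. The mixing is a weighted geometric mean of
the two Dirichlet densities, which stays in the Dirichlet family. The scheme
yields an explicit learning rate ``eta = 1/max(n, 1)`` — the convex weight
on the newest observation — which decays like 1/T in calm stretches and
snaps back towards 1 when a jump is detected (``pi`` near 0).

Jumps are colour-wide, so ``pi`` is inferred from the chosen arm's evidence
and applied to every arm of that colour; the unobserved colour's arms decay
at their prior no-jump probability ``1 - q``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .task import BLUE, COLORS, RED, EnvironmentConfig

__all__ = [
    "DirichletBelief",
    "ColorJumpState",
    "init_belief",
    "no_jump_probability",
    "update_chosen",
    "update_unchosen",
    "posterior_mean",
    "forgetting_operator",
    "expected_value",
    "ForgettingBayesLearner",
]

UNIFORM_CENTER = np.full(3, 1.0 / 3.0)


@dataclass(frozen=True)
class DirichletBelief:
    """Per-arm Dirichlet belief in (c0, nu0, n, z) parameterisation."""

    c0: np.ndarray  #: prior centre, on the 3-simplex
    nu0: float  #: prior precision, > 0
    n: float  #: effective number of observations, >= 0
    z: np.ndarray  #: sufficient statistic, on the 3-simplex

    def __post_init__(self) -> None:
        object.__setattr__(self, "c0", np.asarray(self.c0, dtype=float))
        object.__setattr__(self, "z", np.asarray(self.z, dtype=float))
        if self.nu0 <= 0:
            raise ValueError("prior precision nu0 must be positive")
        if self.n < 0:
            raise ValueError("effective count n must be non-negative")
        for name, v in (("c0", self.c0), ("z", self.z)):
            if v.shape != (3,) or np.any(v < -1e-12) or abs(v.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a probability triplet")

    @property
    def alpha(self) -> np.ndarray:
        """Posterior Dirichlet parameters nu0*c0 + n*z (all > 0)."""
        return self.nu0 * self.c0 + self.n * self.z

    @property
    def eta(self) -> float:
        """Learning rate 1/max(n, 1), the convex weight on a new outcome."""
        return 1.0 / max(self.n, 1.0)


def init_belief(nu0: float = 3.0, c0: np.ndarray | None = None) -> DirichletBelief:
    """Uninformative initial belief: z = c0, one effective observation.

    Defaults (nu0 = 3, uniform c0) give the flat Dirichlet prior scale; the
    posterior mean before any data is c0 and the learning rate is 1.
    """
    c0 = UNIFORM_CENTER.copy() if c0 is None else np.asarray(c0, dtype=float)
    return DirichletBelief(c0=c0, nu0=float(nu0), n=1.0, z=c0.copy())


def no_jump_probability(
    belief: DirichletBelief,
    outcome_index: int,
    q: float,
    evidence_exponent: float = 1.0,
) -> float:
    """Posterior probability pi that no jump occurred, given the outcome.

    A hazard-weighted Bayes factor between two predictive accounts of the
    realised outcome x: staying (posterior predictive alpha_x / sum(alpha))
    versus jumping (reset-prior predictive c0_x)::

        pi = (1-q) * L_stay / ((1-q) * L_stay + q * L_jump)

    pi is decreasing in surprise and equals 1-q when the two predictives
    coincide (no evidence either way — e.g. a fresh or maximally risky
    belief). ``evidence_exponent`` optionally sharpens/flattens the
    predictive ratio; the default 1 uses it as-is.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("hazard q must lie in (0, 1)")
    alpha = belief.alpha
    l_stay = float(alpha[outcome_index] / alpha.sum())
    l_jump = float(belief.c0[outcome_index])
    e = evidence_exponent
    num = (1.0 - q) * l_stay**e
    den = num + q * l_jump**e
    return num / den


def update_chosen(
    belief: DirichletBelief, outcome_index: int, pi: float
) -> DirichletBelief:
    """Forget-then-increment update for the chosen arm.

    The effective count first decays by pi then gains the new observation,
    n' = pi*n + 1, giving the learning-rate recursion eta' = eta/(pi + eta);
    the sufficient statistic moves toward the outcome indicator with weight
    eta': z' = (1 - eta')*z + eta'*e_x. With pi = 1 this is exact conjugate
    updating (eta = 1/T); as pi -> 0 the rate snaps to 1 and z' -> e_x.
    """
    if not 0.0 < pi <= 1.0:
        raise ValueError("pi must lie in (0, 1]")
    n_new = pi * belief.n + 1.0
    eta_new = 1.0 / max(n_new, 1.0)
    z_new = (1.0 - eta_new) * belief.z
    z_new[outcome_index] += eta_new
    return replace(belief, n=n_new, z=z_new)


def update_unchosen(belief: DirichletBelief, pi: float) -> DirichletBelief:
    """Pure decay for an unchosen arm: n' = pi*n, z unchanged.

    No outcome is observed, so only the effective count shrinks; the
    implied ("imaginary") learning rate 1/max(n', 1) creeps back up and the
    posterior mean relaxes toward the prior centre.
    """
    if not 0.0 < pi <= 1.0:
        raise ValueError("pi must lie in (0, 1]")
    return replace(belief, n=pi * belief.n)


def posterior_mean(belief: DirichletBelief) -> np.ndarray:
    """Posterior mean triplet (nu0*c0 + n*z) / (nu0 + n)."""
    return (belief.nu0 * belief.c0 + belief.n * belief.z) / (belief.nu0 + belief.n)


def forgetting_operator(
    alpha_post: np.ndarray, alpha_prior: np.ndarray, pi: float
) -> np.ndarray:
    """Normalised weighted geometric mean of two Dirichlet densities.

    ``f(x) ∝ f_post(x)**pi * f_prior(x)**(1-pi)`` is itself Dirichlet with
    parameters ``pi*alpha_post + (1-pi)*alpha_prior``; pi = 1 keeps the
    no-jump posterior, pi = 0 resets fully to the prior.
    """
    alpha_post = np.asarray(alpha_post, dtype=float)
    alpha_prior = np.asarray(alpha_prior, dtype=float)
    if np.any(alpha_post <= 0) or np.any(alpha_prior <= 0):
        raise ValueError("Dirichlet parameters must be strictly positive")
    if not 0.0 <= pi <= 1.0:
        raise ValueError("pi must lie in [0, 1]")
    return pi * alpha_post + (1.0 - pi) * alpha_prior


def expected_value(belief: DirichletBelief, payoffs) -> float:
    """Expected payoff under the posterior mean: sum_i p_hat_i * payoff_i."""
    return float(posterior_mean(belief) @ np.asarray(payoffs, dtype=float))


@dataclass
class ColorJumpState:
    """Per-colour hazard and the most recent no-jump probability pi."""

    color: str
    q: float  #: prior per-trial jump probability
    pi: float = math.nan  #: most recent no-jump probability

    def __post_init__(self) -> None:
        if not 0.0 < self.q < 1.0:
            raise ValueError("hazard q must lie in (0, 1)")
        if math.isnan(self.pi):
            self.pi = 1.0 - self.q


class ForgettingBayesLearner:
    """Streaming forgetting-Bayesian learner over all six arms.

    The learner holds a :class:`DirichletBelief` per arm and a
    :class:`ColorJumpState` per colour. ``observe`` infers pi from the
    chosen arm's outcome, updates the chosen arm (forget-then-increment),
    decays the same-colour arms by pi, and decays the other colour's arms
    by its prior no-jump probability 1 - q (jumps occur whether or not a
    colour is sampled). Hazards default to the environment's true values.
    """

    n_free_params = 1  # only the softmax inverse temperature is fitted

    def __init__(
        self,
        config: EnvironmentConfig | None = None,
        *,
        nu0: float = 3.0,
        c0: np.ndarray | None = None,
        q_blue: float | None = None,
        q_red: float | None = None,
        evidence_exponent: float = 1.0,
    ) -> None:
        self.config = config or EnvironmentConfig()
        self.colors = self.config.colors
        self.payoffs = self.config.payoff_matrix
        self.nu0 = float(nu0)
        self.c0 = UNIFORM_CENTER.copy() if c0 is None else np.asarray(c0, dtype=float)
        self.q = {
            BLUE: self.config.hazard_blue if q_blue is None else q_blue,
            RED: self.config.hazard_red if q_red is None else q_red,
        }
        self.evidence_exponent = float(evidence_exponent)
        self.reset()

    def reset(self) -> None:
        self.beliefs = [init_belief(self.nu0, self.c0) for _ in range(6)]
        self.jump_states = {c: ColorJumpState(color=c, q=self.q[c]) for c in COLORS}

    # -- read-outs ---------------------------------------------------------

    def alphas(self) -> np.ndarray:
        """(6, 3) posterior Dirichlet parameters."""
        return np.vstack([b.alpha for b in self.beliefs])

    def posterior_means(self) -> np.ndarray:
        """(6, 3) posterior-mean outcome probabilities."""
        return np.vstack([posterior_mean(b) for b in self.beliefs])

    def expected_values(self) -> np.ndarray:
        """(6,) expected payoffs under the posterior means."""
        return np.einsum("ij,ij->i", self.posterior_means(), self.payoffs)

    def estimation_uncertainty(self, metric: str = "variance") -> np.ndarray:
        """(6,) per-arm estimation uncertainty (variance or entropy metric)."""
        from .uncertainty import dirichlet_entropy, dirichlet_variance

        alphas = self.alphas()
        if metric == "variance":
            return dirichlet_variance(alphas)
        if metric == "entropy":
            return dirichlet_entropy(alphas)
        raise ValueError(f"unknown estimation-uncertainty metric {metric!r}")

    # -- updating ----------------------------------------------------------

    def observe(self, arm: int, outcome_index: int, outcome_value=None) -> dict:
        """Assimilate one trial's outcome; returns per-trial diagnostics."""
        color = self.colors[arm]
        other = RED if color == BLUE else BLUE
        pi = no_jump_probability(
            self.beliefs[arm], outcome_index, self.q[color], self.evidence_exponent
        )
        pi_other = 1.0 - self.q[other]
        for j in range(6):
            if j == arm:
                self.beliefs[j] = update_chosen(self.beliefs[j], outcome_index, pi)
            elif self.colors[j] == color:
                self.beliefs[j] = update_unchosen(self.beliefs[j], pi)
            else:
                self.beliefs[j] = update_unchosen(self.beliefs[j], pi_other)
        self.jump_states[color].pi = pi
        self.jump_states[other].pi = pi_other
        return {
            "pi_blue": self.jump_states[BLUE].pi,
            "pi_red": self.jump_states[RED].pi,
            "eta": np.array([b.eta for b in self.beliefs]),
            "n": np.array([b.n for b in self.beliefs]),
        }
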