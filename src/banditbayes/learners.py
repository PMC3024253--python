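"""Model-free comparator learners: Rescorla-Wagner and Pearce-Hall.

Both track a single scalar value per arm, updated from the reward
prediction error of the chosen arm only. The Rescorla-Wagner rule uses a
fixed but colour-specific learning rate (red arms jump more often, so a
separate rate lets the model adapt to average unexpected uncertainty); the
Pearce-Hall extension replaces the fixed rate with a dynamic associability
set by the magnitude of the last prediction error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .task import BLUE, RED, EnvironmentConfig

__all__ = [
    "RWState",
    "PearceHallState",
    "rw_update",
    "pearce_hall_update",
    "RescorlaWagnerLearner",
    "PearceHallLearner",
]

#: maximal payoff magnitude per colour, used to normalise associability
PAYOFF_SCALE = {BLUE: 1.0, RED: 2.0}

_DEFAULT_COLORS = (BLUE, BLUE, BLUE, RED, RED, RED)


@dataclass(frozen=True)
class RWState:
    """Rescorla-Wagner values and colour-specific learning rates."""

    q: np.ndarray = field(default_factory=lambda: np.zeros(6))
    alpha_blue: float = 0.1
    alpha_red: float = 0.1
    colors: tuple[str, ...] = _DEFAULT_COLORS

    def __post_init__(self) -> None:
        object.__setattr__(self, "q", np.asarray(self.q, dtype=float))
        if not (0.0 <= self.alpha_blue <= 1.0 and 0.0 <= self.alpha_red <= 1.0):
            raise ValueError("learning rates must lie in [0, 1]")


def rw_update(state: RWState, chosen_arm: int, outcome_value: float) -> RWState:
    """delta = outcome - Q_chosen; Q_chosen += alpha_color * delta."""
    alpha = (
        state.alpha_blue if state.colors[chosen_arm] == BLUE else state.alpha_red
    )
    q = state.q.copy()
    delta = outcome_value - q[chosen_arm]
    q[chosen_arm] += alpha * delta
    return replace(state, q=q)


@dataclass(frozen=True)
class PearceHallState:
    """Pearce-Hall values and per-arm dynamic learning rates (associability)."""

    q: np.ndarray = field(default_factory=lambda: np.zeros(6))
    assoc: np.ndarray = field(default_factory=lambda: np.ones(6))

    def __post_init__(self) -> None:
        object.__setattr__(self, "q", np.asarray(self.q, dtype=float))
        object.__setattr__(self, "assoc", np.asarray(self.assoc, dtype=float))
        if np.any(self.assoc < 0.0) or np.any(self.assoc > 1.0):
            raise ValueError("associability must lie in [0, 1]")


def pearce_hall_update(
    state: PearceHallState, chosen_arm: int, outcome_value: float, color: str
) -> PearceHallState:
    """Update value with the current associability, then reset associability
    to |delta| normalised by the colour's maximal payoff magnitude.

    Initial associability 1 makes the first outcome fully absorbed; repeated
    identical outcomes drive delta, and hence associability, to zero.
    """
    q = state.q.copy()
    assoc = state.assoc.copy()
    delta = outcome_value - q[chosen_arm]
    q[chosen_arm] += assoc[chosen_arm] * delta
    assoc[chosen_arm] = float(np.clip(abs(delta) / PAYOFF_SCALE[color], 0.0, 1.0))
    return PearceHallState(q=q, assoc=assoc)


class RescorlaWagnerLearner:
    """Streaming Rescorla-Wagner learner (same observe() contract as the
    Bayesian learner; values start at 0, unchosen arms never move)."""

    n_free_params = 3  # beta, alpha_blue, alpha_red

    def __init__(
        self,
        config: EnvironmentConfig | None = None,
        *,
        alpha_blue: float = 0.1,
        alpha_red: float = 0.1,
    ) -> None:
        self.config = config or EnvironmentConfig()
        self.alpha_blue = float(alpha_blue)
        self.alpha_red = float(alpha_red)
        self.reset()

    def reset(self) -> None:
        self.state = RWState(
            alpha_blue=self.alpha_blue,
            alpha_red=self.alpha_red,
            colors=self.config.colors,
        )

    def expected_values(self) -> np.ndarray:
        return self.state.q.copy()

    def estimation_uncertainty(self, metric: str = "variance"):
        raise ValueError(
            "model-free learners carry no posterior belief and hence no "
            "estimation uncertainty"
        )

    def observe(self, arm: int, outcome_index: int, outcome_value: float) -> dict:
        self.state = rw_update(self.state, arm, outcome_value)
        return {"q": self.state.q.copy()}


class PearceHallLearner:
    """Streaming Pearce-Hall learner with dynamic associability."""

    n_free_params = 1  # only beta

    def __init__(self, config: EnvironmentConfig | None = None) -> None:
        self.config = config or EnvironmentConfig()
        self.reset()

    def reset(self) -> None:
        self.state = PearceHallState()

    def expected_values(self) -> np.ndarray:
        return self.state.q.copy()

    def estimation_uncertainty(self, metric: str = "variance"):
        raise ValueError(
            "model-free learners carry no posterior belief and hence no "
            "estimation uncertainty"
        )

    def observe(self, arm: int, outcome_index: int, outcome_value: float) -> dict:
        color = self.config.colors[arm]
        self.state = pearce_hall_update(self.state, arm, outcome_value, color)
        return {"q": self.state.q.copy(), "assoc": self.state.assoc.copy()}
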