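"""Six-arm restless bandit environment and synthetic choice sessions.

The task has six arms in two colour groups of three. Blue arms pay
(-1, 0, +1) CHF, red arms pay (-2, 0, +2) CHF, each according to a latent
probability triplet on the 3-simplex. Within a colour group the triplets
jump *simultaneously* to freshly drawn values at a per-trial hazard rate;
under the defaults the red hazard is four times the blue one. Sessions of
~500 trials are generated either for an arbitrary agent (any learner plus
a softmax choice rule) or replayed from a logged CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

__all__ = [
    "BLUE",
    "RED",
    "COLORS",
    "BLUE_PAYOFFS",
    "RED_PAYOFFS",
    "OUTCOME_LABELS",
    "ArmSpec",
    "EnvironmentConfig",
    "EnvironmentState",
    "default_arm_specs",
    "draw_arm_probabilities",
    "initial_state",
    "step",
    "simulate_agent_session",
    "read_session",
    "write_session",
    "validate_session",
]

BLUE = "blue"
RED = "red"
COLORS = (BLUE, RED)

BLUE_PAYOFFS = (-1.0, 0.0, 1.0)
RED_PAYOFFS = (-2.0, 0.0, 2.0)

#: outcome_index coding: loss=0, zero=1, gain=2
OUTCOME_LABELS = ("loss", "zero", "gain")

ENTROPY_PROFILES = ("biased", "intermediate", "random")

_SIMPLEX_ATOL = 1e-12


@dataclass(frozen=True)
class ArmSpec:
    """One bandit arm: colour, payoff triple and jump-target entropy profile."""

    arm_id: int
    color: str
    payoffs: tuple[float, float, float]
    entropy_profile: str = "random"

    def __post_init__(self) -> None:
        if not 0 <= self.arm_id <= 5:
            raise ValueError(f"arm_id must be in 0..5, got {self.arm_id}")
        if self.color not in COLORS:
            raise ValueError(f"color must be one of {COLORS}, got {self.color!r}")
        if self.entropy_profile not in ENTROPY_PROFILES:
            raise ValueError(
                f"entropy_profile must be one of {ENTROPY_PROFILES}, "
                f"got {self.entropy_profile!r}"
            )
        expected = BLUE_PAYOFFS if self.color == BLUE else RED_PAYOFFS
        if tuple(self.payoffs) != expected:
            raise ValueError(
                f"{self.color} arms pay {expected}, got {tuple(self.payoffs)}"
            )
        if not (self.payoffs[0] < self.payoffs[1] < self.payoffs[2]):
            raise ValueError("payoff triple must be strictly increasing")


def default_arm_specs() -> tuple[ArmSpec, ...]:
    """Three blue arms (0-2) then three red arms (3-5).

    Within each colour group one arm is 'biased' (low-entropy jump targets),
    one 'intermediate' and one 'random' (near-uniform targets), mirroring a
    board in which one location of each colour is predictable and another is
    close to random.
    """
    specs = []
    for i, color in enumerate((BLUE, BLUE, BLUE, RED, RED, RED)):
        payoffs = BLUE_PAYOFFS if color == BLUE else RED_PAYOFFS
        specs.append(
            ArmSpec(
                arm_id=i,
                color=color,
                payoffs=payoffs,
                entropy_profile=ENTROPY_PROFILES[i % 3],
            )
        )
    return tuple(specs)


@dataclass(frozen=True)
class EnvironmentConfig:
    """Generative configuration of the restless bandit.

    Hazards are per-trial jump probabilities per colour group; the defaults
    preserve the 4x red/blue hazard ratio of the task.
    """

    n_trials: int = 500
    hazard_blue: float = 0.04
    hazard_red: float = 0.16
    arm_specs: tuple[ArmSpec, ...] = field(default_factory=default_arm_specs)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not (0.0 <= self.hazard_blue <= 1.0 and 0.0 <= self.hazard_red <= 1.0):
            raise ValueError("hazards must lie in [0, 1]")
        if len(self.arm_specs) != 6:
            raise ValueError("exactly 6 arms are required")
        for color in COLORS:
            if sum(s.color == color for s in self.arm_specs) != 3:
                raise ValueError(f"exactly 3 arms must be {color}")
        if [s.arm_id for s in self.arm_specs] != list(range(6)):
            raise ValueError("arm_specs must be ordered by arm_id 0..5")

    @property
    def colors(self) -> tuple[str, ...]:
        return tuple(s.color for s in self.arm_specs)

    @property
    def payoff_matrix(self) -> np.ndarray:
        """(6, 3) array of (loss, zero, gain) payoffs per arm."""
        return np.array([s.payoffs for s in self.arm_specs], dtype=float)

    def hazard(self, color: str) -> float:
        return self.hazard_blue if color == BLUE else self.hazard_red

    def arms_of_color(self, color: str) -> list[int]:
        return [s.arm_id for s in self.arm_specs if s.color == color]

    def to_dict(self) -> dict:
        return {
            "n_trials": self.n_trials,
            "hazard_blue": self.hazard_blue,
            "hazard_red": self.hazard_red,
            "seed": self.seed,
            "arm_specs": [
                {
                    "arm_id": s.arm_id,
                    "color": s.color,
                    "payoffs": list(s.payoffs),
                    "entropy_profile": s.entropy_profile,
                }
                for s in self.arm_specs
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnvironmentConfig":
        kwargs = dict(d)
        specs = kwargs.pop("arm_specs", None)
        if specs is not None:
            kwargs["arm_specs"] = tuple(
                ArmSpec(
                    arm_id=s["arm_id"],
                    color=s["color"],
                    payoffs=tuple(s["payoffs"]),
                    entropy_profile=s.get("entropy_profile", "random"),
                )
                for s in specs
            )
        return cls(**kwargs)


@dataclass
class EnvironmentState:
    """Latent per-arm outcome-probability triplets at a given trial."""

    probs: np.ndarray  # (6, 3), each row on the 3-simplex
    trial_index: int = 0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (6, 3):
            raise ValueError("probs must have shape (6, 3)")
        if np.any(self.probs < 0) or np.any(
            np.abs(self.probs.sum(axis=1) - 1.0) > 1e-9
        ):
            raise ValueError("each probability triplet must lie on the 3-simplex")
        # renormalise away accumulated float error so stored rows sum to 1
        self.probs = self.probs / self.probs.sum(axis=1, keepdims=True)


def draw_arm_probabilities(spec: ArmSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw a fresh outcome-probability triplet for an arm after a jump.

    Samplers by entropy profile:

    - ``random``: symmetric Dirichlet(1,1,1) (uniform on the simplex);
    - ``intermediate``: Dirichlet(2,2,2);
    - ``biased``: one outcome (picked uniformly) receives a probability drawn
      uniformly from [0.7, 0.9]; the remaining mass is split uniformly
      between the other two outcomes.

    'biased' triplets have lower entropy than 'random' ones in expectation.
    """
    if spec.entropy_profile == "random":
        p = rng.dirichlet(np.ones(3))
    elif spec.entropy_profile == "intermediate":
        p = rng.dirichlet(np.full(3, 2.0))
    else:  # biased
        hi = rng.uniform(0.7, 0.9)
        split = rng.uniform()
        rest = 1.0 - hi
        which = rng.integers(3)
        p = np.empty(3)
        others = [i for i in range(3) if i != which]
        p[which] = hi
        p[others[0]] = rest * split
        p[others[1]] = rest * (1.0 - split)
    return p / p.sum()


def initial_state(
    config: EnvironmentConfig, rng: np.random.Generator
) -> EnvironmentState:
    probs = np.vstack([draw_arm_probabilities(s, rng) for s in config.arm_specs])
    return EnvironmentState(probs=probs, trial_index=0)


def step(
    state: EnvironmentState,
    config: EnvironmentConfig,
    chosen_arm: int,
    rng: np.random.Generator,
) -> tuple[int, EnvironmentState, dict[str, bool]]:
    """Advance the environment one trial.

    Jumps are resolved per colour *before* the outcome is drawn, so the
    outcome reflects post-jump probabilities. Within a colour group either
    all arms receive fresh triplets or none do.

    Returns ``(outcome_index, new_state, jump_flags)`` with outcome_index
    coded loss=0, zero=1, gain=2 and ``jump_flags`` keyed by colour.
    """
    if not (isinstance(chosen_arm, (int, np.integer)) and 0 <= chosen_arm <= 5):
        raise ValueError(f"chosen_arm must be an integer in 0..5, got {chosen_arm!r}")
    probs = state.probs.copy()
    jump_flags: dict[str, bool] = {}
    for color in COLORS:  # fixed order keeps the RNG stream reproducible
        jumped = rng.random() < config.hazard(color)
        jump_flags[color] = bool(jumped)
        if jumped:
            for j in config.arms_of_color(color):
                probs[j] = draw_arm_probabilities(config.arm_specs[j], rng)
    outcome_index = int(rng.choice(3, p=probs[chosen_arm]))
    new_state = EnvironmentState(probs=probs, trial_index=state.trial_index + 1)
    return outcome_index, new_state, jump_flags


#: SessionLog core columns (trials are 1-based in logs).
SESSION_COLUMNS = ["trial", "arm", "color", "outcome_value", "outcome_index"]


def simulate_agent_session(
    config: EnvironmentConfig,
    agent,
    seed: int | None = None,
    record_latent: bool = True,
) -> pd.DataFrame:
    """Simulate a full session of an agent playing the bandit.

    ``agent`` must expose ``reset()``, ``choice_probs() -> (6,)`` and
    ``observe(arm, outcome_index, outcome_value)``. The environment and the
    agent's choice sampling consume independent RNG sub-streams, so swapping
    agents does not perturb the environment's jump/outcome sequence.

    With ``record_latent`` the log also carries the chosen arm's post-jump
    triplet (``p_loss``/``p_zero``/``p_gain``), per-colour jump indicators
    and every arm's latent triplet (``p{j}_loss`` etc.) for diagnostics.
    """
    root = np.random.default_rng(config.seed if seed is None else seed)
    env_rng, agent_rng = root.spawn(2)
    state = initial_state(config, env_rng)
    agent.reset()
    payoffs = config.payoff_matrix
    colors = config.colors
    rows = []
    for trial in range(1, config.n_trials + 1):
        p_choice = np.asarray(agent.choice_probs(), dtype=float)
        if not np.all(np.isfinite(p_choice)):
            raise FloatingPointError(
                f"non-finite agent choice probabilities at trial {trial}"
            )
        arm = int(agent_rng.choice(6, p=p_choice))
        outcome_index, state, jumps = step(state, config, arm, env_rng)
        outcome_value = float(payoffs[arm, outcome_index])
        row = {
            "trial": trial,
            "arm": arm,
            "color": colors[arm],
            "outcome_value": outcome_value,
            "outcome_index": outcome_index,
        }
        if record_latent:
            row["p_loss"], row["p_zero"], row["p_gain"] = state.probs[arm]
            row["jump_blue"] = int(jumps[BLUE])
            row["jump_red"] = int(jumps[RED])
            for j in range(6):
                for k, lab in enumerate(OUTCOME_LABELS):
                    row[f"p{j}_{lab}"] = state.probs[j, k]
        rows.append(row)
        agent.observe(arm, outcome_index, outcome_value)
    return pd.DataFrame(rows)


def write_session(session: pd.DataFrame, path) -> None:
    session.to_csv(path, index=False)


def read_session(path) -> pd.DataFrame:
    session = pd.read_csv(path)
    missing = [c for c in SESSION_COLUMNS if c not in session.columns]
    if missing:
        raise ValueError(f"session log is missing columns {missing}")
    return session


def validate_session(
    session: pd.DataFrame, config: EnvironmentConfig | None = None
) -> None:
    """Raise if a session log violates the task's structural invariants."""
    config = config or EnvironmentConfig()
    payoffs = config.payoff_matrix
    arms = session["arm"].to_numpy()
    if arms.min() < 0 or arms.max() > 5:
        raise ValueError("arm indices must lie in 0..5")
    idx = session["outcome_index"].to_numpy()
    if idx.min() < 0 or idx.max() > 2:
        raise ValueError("outcome_index must lie in 0..2")
    expected = payoffs[arms, idx]
    if not np.allclose(expected, session["outcome_value"].to_numpy()):
        raise ValueError("outcome_value inconsistent with chosen arm's payoffs")
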