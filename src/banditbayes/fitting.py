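"""Softmax choice models, session likelihoods, ML fitting and BIC comparison.

A choice model pairs a learner (forgetting-Bayesian, Rescorla-Wagner or
Pearce-Hall) with a softmax rule over (possibly ambiguity-adjusted) option
values. In the bonus/penalty variants the value entering the softmax is the
weighted average of the expected payoff Q and the arm's estimation
uncertainty U:

    V = (1 - w) * Q + w * U   (bonus)      V = (1 - w) * Q - w * U   (penalty)

with w = 1/2 by default. Bonus/penalty only make sense for the Bayesian
learner — model-free learners carry no posterior, hence no estimation
uncertainty.

Fitting is per subject (session): the session is replayed causally, the
log-likelihood of the observed choices is maximised over the free
parameters (beta; plus the two colour-specific learning rates for RW) by a
deterministic grid search with bounded local refinement, and models are
compared by BIC = -2 LL + k ln(n) with paired t-tests across subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp

from .bayes import ForgettingBayesLearner
from .learners import PearceHallLearner, RescorlaWagnerLearner
from .task import BLUE, EnvironmentConfig

__all__ = [
    "ChoiceModelSpec",
    "FitResult",
    "ModelComparison",
    "SoftmaxAgent",
    "softmax_probs",
    "adjusted_value",
    "make_learner",
    "value_trajectory",
    "session_loglik",
    "fit_subject",
    "compare_models",
]

LEARNERS = ("bayes", "rw", "pearce_hall")
VALUATIONS = ("base", "bonus", "penalty")
METRICS = ("variance", "entropy")

BETA_BOUNDS = (1e-3, 50.0)
ALPHA_BOUNDS = (0.0, 1.0)
PROB_FLOOR = 1e-12

#: deterministic search grids: beta log-spaced, learning rates linear
BETA_GRID = np.geomspace(0.01, 50.0, 50)
ALPHA_GRID = np.linspace(0.0, 1.0, 21)


@dataclass(frozen=True)
class ChoiceModelSpec:
    """A learner plus a softmax valuation rule.

    ``valuation`` is 'base' (expected payoff only), 'bonus' (exploration
    bonus equal to estimation uncertainty) or 'penalty' (ambiguity
    penalty); ``uncertainty_metric`` selects the variance or entropy
    measure; ``w`` is the bonus/penalty weight.
    """

    learner: str
    valuation: str = "base"
    uncertainty_metric: str = "variance"
    w: float = 0.5

    def __post_init__(self) -> None:
        if self.learner not in LEARNERS:
            raise ValueError(f"learner must be one of {LEARNERS}")
        if self.valuation not in VALUATIONS:
            raise ValueError(f"valuation must be one of {VALUATIONS}")
        if self.uncertainty_metric not in METRICS:
            raise ValueError(f"uncertainty_metric must be one of {METRICS}")
        if self.valuation != "base" and self.learner != "bayes":
            raise ValueError(
                "bonus/penalty valuation requires the Bayesian learner: "
                "estimation uncertainty is undefined for model-free learners"
            )
        if not 0.0 < self.w < 1.0:
            raise ValueError("w must lie in (0, 1)")

    @property
    def name(self) -> str:
        if self.learner == "bayes":
            return f"bayes-{self.valuation}"
        return {"rw": "rw", "pearce_hall": "pearce-hall"}[self.learner]

    @property
    def n_free_params(self) -> int:
        """beta, plus alpha_blue and alpha_red for RW."""
        return 3 if self.learner == "rw" else 1

    @classmethod
    def from_name(cls, name: str, **kwargs) -> "ChoiceModelSpec":
        name = name.strip().lower()
        if name.startswith("bayes"):
            valuation = name.split("-", 1)[1] if "-" in name else "base"
            return cls(learner="bayes", valuation=valuation, **kwargs)
        if name in ("rw", "reinforcement-learning"):
            return cls(learner="rw", **kwargs)
        if name in ("pearce-hall", "pearce_hall", "ph"):
            return cls(learner="pearce_hall", **kwargs)
        raise ValueError(f"unknown model name {name!r}")


def softmax_probs(values, beta: float) -> np.ndarray:
    """Softmax choice probabilities p_i = exp(beta V_i)/sum_j exp(beta V_j).

    Overflow-safe via max subtraction; invariant to adding a constant to
    all values; beta = 0 gives the uniform distribution.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise FloatingPointError("non-finite option values in softmax")
    if beta < 0:
        raise ValueError("beta must be non-negative")
    z = beta * (values - values.max())
    e = np.exp(z)
    return e / e.sum()


def adjusted_value(q, u, mode: str, w: float = 0.5):
    """Ambiguity-adjusted option value.

    base -> Q;  bonus -> (1-w) Q + w U;  penalty -> (1-w) Q - w U.
    """
    q = np.asarray(q, dtype=float)
    if mode == "base":
        return q
    u = np.asarray(u, dtype=float)
    if mode == "bonus":
        return (1.0 - w) * q + w * u
    if mode == "penalty":
        return (1.0 - w) * q - w * u
    raise ValueError(f"unknown valuation mode {mode!r}")


def make_learner(
    spec: ChoiceModelSpec,
    params: dict | None = None,
    config: EnvironmentConfig | None = None,
):
    """Instantiate the learner of a model spec with its learner parameters."""
    params = params or {}
    config = config or EnvironmentConfig()
    if spec.learner == "bayes":
        return ForgettingBayesLearner(
            config,
            q_blue=params.get("q_blue"),
            q_red=params.get("q_red"),
        )
    if spec.learner == "rw":
        return RescorlaWagnerLearner(
            config,
            alpha_blue=params.get("alpha_blue", 0.1),
            alpha_red=params.get("alpha_red", 0.1),
        )
    return PearceHallLearner(config)


class SoftmaxAgent:
    """Generative agent: a learner plus softmax over adjusted values.

    Used by :func:`banditbayes.task.simulate_agent_session` to produce
    synthetic choice data with known parameters.
    """

    def __init__(self, spec: ChoiceModelSpec, params: dict, config=None) -> None:
        self.spec = spec
        self.params = dict(params)
        self.beta = float(params["beta"])
        self.config = config or EnvironmentConfig()
        self.learner = make_learner(spec, self.params, self.config)

    def reset(self) -> None:
        self.learner.reset()

    def _values(self) -> np.ndarray:
        q = self.learner.expected_values()
        if self.spec.valuation == "base":
            return q
        u = self.learner.estimation_uncertainty(self.spec.uncertainty_metric)
        return adjusted_value(q, u, self.spec.valuation, self.spec.w)

    def choice_probs(self) -> np.ndarray:
        return softmax_probs(self._values(), self.beta)

    def observe(self, arm: int, outcome_index: int, outcome_value: float):
        return self.learner.observe(arm, outcome_index, outcome_value)


# ---------------------------------------------------------------------------
# Likelihood machinery


def _session_arrays(session: pd.DataFrame):
    arms = session["arm"].to_numpy(dtype=int)
    idx = session["outcome_index"].to_numpy(dtype=int)
    vals = session["outcome_value"].to_numpy(dtype=float)
    return arms, idx, vals


def value_trajectory(
    spec: ChoiceModelSpec,
    params: dict | None,
    session: pd.DataFrame,
    config: EnvironmentConfig | None = None,
) -> np.ndarray:
    """(T, 6) adjusted option values *before* each trial's outcome.

    Replays the learner causally over the logged (arm, outcome) sequence;
    row t holds the values from which trial t's choice probabilities are
    formed, so the likelihood at t conditions only on trials < t.
    """
    config = config or EnvironmentConfig()
    learner = make_learner(spec, params, config)
    learner.reset()
    arms, idx, vals = _session_arrays(session)
    T = len(arms)
    V = np.empty((T, 6))
    for t in range(T):
        q = learner.expected_values()
        if spec.valuation == "base":
            V[t] = q
        else:
            u = learner.estimation_uncertainty(spec.uncertainty_metric)
            V[t] = adjusted_value(q, u, spec.valuation, spec.w)
        learner.observe(arms[t], idx[t], vals[t])
    return V


def _loglik_from_values(V: np.ndarray, choices: np.ndarray, beta) -> np.ndarray:
    """Log-likelihood(s) of the observed choices for one or many betas.

    Per-trial log-probabilities are floored at ln(1e-12) so extreme betas
    during search keep the objective finite.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    z = beta[:, None, None] * V[None, :, :]  # (B, T, 6)
    lse = logsumexp(z, axis=2)
    ll_t = z[:, np.arange(V.shape[0]), choices] - lse
    floored = ll_t < np.log(PROB_FLOOR)
    if np.any(floored):
        warnings.warn(
            "some per-trial choice probabilities fell below 1e-12 and were "
            "floored",
            RuntimeWarning,
            stacklevel=3,
        )
        ll_t = np.maximum(ll_t, np.log(PROB_FLOOR))
    return ll_t.sum(axis=1)


def session_loglik(
    spec: ChoiceModelSpec,
    params: dict,
    session: pd.DataFrame,
    config: EnvironmentConfig | None = None,
) -> float:
    """Sum over trials of ln P(chosen arm | history), replayed causally."""
    if len(session) == 0:
        raise ValueError("session is empty")
    V = value_trajectory(spec, params, session, config)
    choices = session["arm"].to_numpy(dtype=int)
    return float(_loglik_from_values(V, choices, params["beta"])[0])


def per_trial_choice_probs(
    spec: ChoiceModelSpec,
    params: dict,
    session: pd.DataFrame,
    config: EnvironmentConfig | None = None,
) -> np.ndarray:
    """(T, 6) softmax choice probabilities at the given parameters."""
    V = value_trajectory(spec, params, session, config)
    beta = float(params["beta"])
    z = beta * (V - V.max(axis=1, keepdims=True))
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _rw_value_grid(
    session: pd.DataFrame, config: EnvironmentConfig, ab_grid, ar_grid
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """RW value trajectories for a whole (alpha_blue, alpha_red) grid.

    Returns (V, AB, AR): V has shape (T, P, 6) where P enumerates grid
    pairs; AB/AR give each pair's learning rates. Vectorising over the
    grid keeps the 21x21 scan fast.
    """
    ab_grid = np.asarray(ab_grid, dtype=float)
    ar_grid = np.asarray(ar_grid, dtype=float)
    AB, AR = np.meshgrid(ab_grid, ar_grid, indexing="ij")
    AB, AR = AB.ravel(), AR.ravel()
    is_blue = np.array([c == BLUE for c in config.colors])
    arms, _, vals = _session_arrays(session)
    T, P = len(arms), len(AB)
    Q = np.zeros((P, 6))
    V = np.empty((T, P, 6))
    for t in range(T):
        V[t] = Q
        a = arms[t]
        rate = AB if is_blue[a] else AR
        Q[:, a] += rate * (vals[t] - Q[:, a])
    return V, AB, AR


@dataclass
class FitResult:
    """Per-subject maximum-likelihood fit of one choice model."""

    model: ChoiceModelSpec
    params: dict
    loglik: float
    bic: float
    n_trials: int
    per_trial_choice_probs: np.ndarray | None = None
    converged: bool = True
    subject: int | str | None = None

    def to_dict(self) -> dict:
        return {
            "model": self.model.name,
            "params": {k: float(v) for k, v in self.params.items()},
            "loglik": float(self.loglik),
            "bic": float(self.bic),
            "n_trials": int(self.n_trials),
            "converged": bool(self.converged),
            "subject": self.subject,
        }


def _bic(loglik: float, k: int, n: int) -> float:
    return -2.0 * loglik + k * np.log(n)


def fit_subject(
    spec: ChoiceModelSpec,
    session: pd.DataFrame,
    config: EnvironmentConfig | None = None,
    *,
    keep_choice_probs: bool = True,
    subject: int | str | None = None,
) -> FitResult:
    """Maximum-likelihood fit of one model to one session.

    Deterministic: a coarse grid (beta log-spaced over (0, 50]; learning
    rates linear over [0, 1] for RW) followed by bounded local refinement.
    If refinement fails to improve on the grid, the best grid point is
    returned with ``converged=False``.
    """
    config = config or EnvironmentConfig()
    T = len(session)
    if T == 0:
        raise ValueError("session is empty")
    if T < 50:
        warnings.warn(
            f"session has only {T} trials; parameter estimates will be noisy",
            UserWarning,
            stacklevel=2,
        )
    choices = session["arm"].to_numpy(dtype=int)

    if spec.learner == "rw":
        V_grid, AB, AR = _rw_value_grid(session, config, ALPHA_GRID, ALPHA_GRID)
        # grid scan in float32 with reused buffers; the winner is re-scored
        # in float64 below, so selection precision is all that matters here
        V32 = V_grid.astype(np.float32)
        P = len(AB)
        Vc = V32[np.arange(T)[:, None], np.arange(P)[None, :], choices[:, None]]
        z = np.empty_like(V32)
        buf = np.empty_like(V32)
        floor32 = np.float32(np.log(PROB_FLOOR))
        best_ll, best_p, best_beta = -np.inf, 0, float(BETA_GRID[0])
        for beta in BETA_GRID:
            np.multiply(V32, np.float32(beta), out=z)
            m = z.max(axis=2)
            np.exp(z - m[:, :, None], out=buf)
            lse = m + np.log(buf.sum(axis=2))
            ll = np.maximum(np.float32(beta) * Vc - lse, floor32).sum(axis=0)
            p_best = int(np.argmax(ll))
            if ll[p_best] > best_ll:
                best_ll, best_p, best_beta = float(ll[p_best]), p_best, float(beta)
        params_grid = {
            "beta": best_beta,
            "alpha_blue": float(AB[best_p]),
            "alpha_red": float(AR[best_p]),
        }
        ll_grid = float(
            _loglik_from_values(V_grid[:, best_p, :], choices, best_beta)[0]
        )

        def neg_ll(x):
            beta, ab, ar = x
            V = _rw_value_grid(session, config, [ab], [ar])[0][:, 0, :]
            return -_loglik_from_values(V, choices, beta)[0]

        x0 = [params_grid["beta"], params_grid["alpha_blue"], params_grid["alpha_red"]]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = optimize.minimize(
                neg_ll,
                x0,
                method="L-BFGS-B",
                bounds=[BETA_BOUNDS, ALPHA_BOUNDS, ALPHA_BOUNDS],
            )
        if res.success and -res.fun >= ll_grid:
            params = {
                "beta": float(res.x[0]),
                "alpha_blue": float(res.x[1]),
                "alpha_red": float(res.x[2]),
            }
            loglik, converged = float(-res.fun), True
        else:
            params, loglik, converged = params_grid, ll_grid, False
    else:
        V = value_trajectory(spec, None, session, config)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ll_grid_all = _loglik_from_values(V, choices, BETA_GRID)
            b_best = int(np.argmax(ll_grid_all))
            ll_grid = float(ll_grid_all[b_best])
            lo = BETA_GRID[max(b_best - 1, 0)]
            hi = BETA_GRID[min(b_best + 1, len(BETA_GRID) - 1)]
            res = optimize.minimize_scalar(
                lambda b: -_loglik_from_values(V, choices, b)[0],
                bounds=(max(lo, BETA_BOUNDS[0]), min(hi, BETA_BOUNDS[1])),
                method="bounded",
            )
        if res.fun is not None and -res.fun >= ll_grid:
            params = {"beta": float(res.x)}
            loglik, converged = float(-res.fun), True
        else:
            params = {"beta": float(BETA_GRID[b_best])}
            loglik, converged = ll_grid, False

    probs = (
        per_trial_choice_probs(spec, params, session, config)
        if keep_choice_probs
        else None
    )
    return FitResult(
        model=spec,
        params=params,
        loglik=loglik,
        bic=_bic(loglik, spec.n_free_params, T),
        n_trials=T,
        per_trial_choice_probs=probs,
        converged=converged,
        subject=subject,
    )


# ---------------------------------------------------------------------------
# Cohort-level model comparison


@dataclass
class ModelComparison:
    """Paired BIC comparison of two models across the same subjects."""

    model_a: str
    model_b: str
    n_subjects: int
    mean_bic_a: float
    mean_bic_b: float
    sd_bic_a: float
    sd_bic_b: float
    mean_diff: float  #: mean of BIC_a - BIC_b (negative favours model a)
    sd_diff: float
    t_stat: float
    p_value: float
    frac_a: float  #: fraction of subjects with lower BIC under model a
    frac_b: float
    frac_tie: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def compare_models(
    fits_a: list[FitResult], fits_b: list[FitResult]
) -> ModelComparison:
    """Per-subject BIC differences, paired t-test and preference fractions.

    Subjects must match one-to-one between the two fit lists (checked via
    the ``subject`` labels when present). Identical fits yield t = 0,
    p = 1 and a tie, without error.
    """
    if len(fits_a) != len(fits_b) or not fits_a:
        raise ValueError("fit lists must be non-empty and of equal length")
    subj_a = [f.subject for f in fits_a]
    subj_b = [f.subject for f in fits_b]
    if any(s is not None for s in subj_a + subj_b) and subj_a != subj_b:
        raise ValueError("mismatched subject sets between models")
    bic_a = np.array([f.bic for f in fits_a])
    bic_b = np.array([f.bic for f in fits_b])
    diff = bic_a - bic_b
    sd_diff = float(diff.std(ddof=1)) if len(diff) > 1 else 0.0
    if sd_diff == 0.0:
        t_stat, p_value = 0.0, 1.0
    else:
        t_stat, p_value = stats.ttest_rel(bic_a, bic_b)
        t_stat, p_value = float(t_stat), float(p_value)
    return ModelComparison(
        model_a=fits_a[0].model.name,
        model_b=fits_b[0].model.name,
        n_subjects=len(diff),
        mean_bic_a=float(bic_a.mean()),
        mean_bic_b=float(bic_b.mean()),
        sd_bic_a=float(bic_a.std(ddof=1)) if len(bic_a) > 1 else 0.0,
        sd_bic_b=float(bic_b.std(ddof=1)) if len(bic_b) > 1 else 0.0,
        mean_diff=float(diff.mean()),
        sd_diff=sd_diff,
        t_stat=t_stat,
        p_value=p_value,
        frac_a=float(np.mean(diff < 0)),
        frac_b=float(np.mean(diff > 0)),
        frac_tie=float(np.mean(diff == 0)),
    )
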