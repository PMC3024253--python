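"""End-to-end studies: cohort simulation, model recovery, diagnostics.

These drive the full pipeline — simulate synthetic cohorts from a
generating model with known parameters, fit a set of candidate models to
every session, and summarise the comparison (BIC tables, paired t-tests,
best-model confusion counts). Everything is deterministic given the
config's seed; per-subject failures are isolated and logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bayes import ForgettingBayesLearner
from .fitting import (
    ChoiceModelSpec,
    FitResult,
    ModelComparison,
    SoftmaxAgent,
    compare_models,
    fit_subject,
)
from .task import EnvironmentConfig, simulate_agent_session
from .uncertainty import dirichlet_entropy, dirichlet_variance, risk_entropy

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "RecoveryResult",
    "simulate_cohort",
    "run_recovery",
    "replay_diagnostics",
]


def _draw_params(param_spec: dict, rng: np.random.Generator) -> dict:
    """Fixed scalars pass through; (low, high) pairs draw uniformly."""
    out = {}
    for k, v in param_spec.items():
        if isinstance(v, (tuple, list)) and len(v) == 2:
            out[k] = float(rng.uniform(v[0], v[1]))
        else:
            out[k] = float(v)
    return out


@dataclass
class ExperimentConfig:
    """Configuration of a simulate-and-fit recovery study."""

    generating_model: ChoiceModelSpec
    generating_params: dict = field(default_factory=lambda: {"beta": 5.0})
    models_to_fit: tuple[str, ...] = ("bayes-base", "bayes-penalty", "rw")
    n_subjects: int = 30
    n_trials: int = 500
    env: EnvironmentConfig | None = None
    seed: int = 0
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_trials < 1:
            raise ValueError("n_subjects and n_trials must be >= 1")
        for name in self.models_to_fit:
            ChoiceModelSpec.from_name(name)  # raises on unknown models


@dataclass
class RecoveryResult:
    """Fits per model, summary table and pairwise comparisons."""

    fits: dict[str, list[FitResult]]
    table: pd.DataFrame  #: one row per (subject, model)
    comparisons: dict[tuple[str, str], ModelComparison]
    best_counts: dict[str, int]  #: subjects best fit (lowest BIC) per model
    true_params: list[dict]
    failures: list[tuple[int, str]]


def simulate_cohort(config: ExperimentConfig):
    """Simulate ``n_subjects`` sessions from the generating model.

    Returns (sessions, true_params); subject k uses seed seed + k for the
    environment/choice streams so cohorts are reproducible yet varied.
    """
    env = config.env or EnvironmentConfig(n_trials=config.n_trials)
    if env.n_trials != config.n_trials:
        env = EnvironmentConfig(**{**env.to_dict(), "n_trials": config.n_trials})
    param_rng = np.random.default_rng(config.seed)
    sessions, true_params = [], []
    for k in range(config.n_subjects):
        params = _draw_params(config.generating_params, param_rng)
        agent = SoftmaxAgent(config.generating_model, params, env)
        sessions.append(
            simulate_agent_session(env, agent, seed=config.seed + k + 1)
        )
        true_params.append(params)
    return sessions, true_params


def run_recovery(config: ExperimentConfig) -> RecoveryResult:
    """Simulate a cohort, fit all candidate models, compare by BIC."""
    env = config.env or EnvironmentConfig(n_trials=config.n_trials)
    sessions, true_params = simulate_cohort(config)
    logger.info(
        "recovery: %d subjects x %d trials generated by %s",
        config.n_subjects,
        config.n_trials,
        config.generating_model.name,
    )
    fits: dict[str, list[FitResult]] = {m: [] for m in config.models_to_fit}
    failures: list[tuple[int, str]] = []
    rows = []
    for k, session in enumerate(sessions):
        for name in config.models_to_fit:
            spec = ChoiceModelSpec.from_name(name)
            try:
                fit = fit_subject(
                    spec, session, env, keep_choice_probs=False, subject=k
                )
            except Exception as exc:  # isolate per-subject failures
                logger.warning("subject %d, model %s failed: %s", k, name, exc)
                failures.append((k, name))
                continue
            fits[name].append(fit)
            rows.append(
                {
                    "subject": k,
                    "model": name,
                    "loglik": fit.loglik,
                    "bic": fit.bic,
                    **{f"hat_{p}": v for p, v in fit.params.items()},
                }
            )
    table = pd.DataFrame(rows)
    comparisons = {}
    names = list(config.models_to_fit)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if len(fits[a]) == len(fits[b]) and fits[a]:
                comparisons[(a, b)] = compare_models(fits[a], fits[b])
    best_counts = dict.fromkeys(names, 0)
    if not table.empty:
        for _, sub in table.groupby("subject"):
            best_counts[sub.loc[sub["bic"].idxmin(), "model"]] += 1
    result = RecoveryResult(
        fits=fits,
        table=table,
        comparisons=comparisons,
        best_counts=best_counts,
        true_params=true_params,
        failures=failures,
    )
    if config.out_dir is not None:
        _write_recovery(result, config)
    return result


def _write_recovery(result: RecoveryResult, config: ExperimentConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.table.to_csv(out / "fits.csv", index=False)
    comp_rows = [c.to_dict() for c in result.comparisons.values()]
    pd.DataFrame(comp_rows).to_csv(out / "comparisons.csv", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(
            {
                "generating_model": config.generating_model.name,
                "n_subjects": config.n_subjects,
                "n_trials": config.n_trials,
                "seed": config.seed,
                "best_counts": result.best_counts,
                "failures": result.failures,
            },
            fh,
            indent=2,
        )
    logger.info("recovery outputs written to %s", out)


def replay_diagnostics(
    session: pd.DataFrame,
    learner: ForgettingBayesLearner | None = None,
    config: EnvironmentConfig | None = None,
) -> pd.DataFrame:
    """Replay a session through the Bayesian learner, logging trajectories.

    Per trial: the no-jump probabilities per colour, and per arm the
    learning rate, effective count, estimated risk (entropy of the
    posterior mean) and both estimation-uncertainty metrics — the raw
    material for the trajectory plots.
    """
    config = config or EnvironmentConfig()
    learner = learner or ForgettingBayesLearner(config)
    learner.reset()
    rows = []
    for rec in session.itertuples(index=False):
        alphas = learner.alphas()
        means = learner.posterior_means()
        row = {
            "trial": rec.trial,
            "arm": rec.arm,
            "color": rec.color,
            "outcome_value": rec.outcome_value,
        }
        est_var = dirichlet_variance(alphas)
        est_ent = dirichlet_entropy(alphas)
        for j in range(6):
            row[f"risk_{j}"] = risk_entropy(means[j])
            row[f"est_var_{j}"] = est_var[j]
            row[f"est_ent_{j}"] = est_ent[j]
            row[f"eta_{j}"] = learner.beliefs[j].eta
            row[f"n_{j}"] = learner.beliefs[j].n
        row["est_var_chosen"] = est_var[rec.arm]
        row["est_ent_chosen"] = est_ent[rec.arm]
        diag = learner.observe(rec.arm, rec.outcome_index, rec.outcome_value)
        row["pi_blue"] = diag["pi_blue"]
        row["pi_red"] = diag["pi_red"]
        rows.append(row)
    return pd.DataFrame(rows)
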