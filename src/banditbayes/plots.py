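"""Diagnostic trajectory plots for simulated or replayed sessions.

Four views of a session replayed through the Bayesian learner: the
estimation-uncertainty sawtooth of the chosen arm, the no-jump probability
trace against true jump trials, per-arm mean estimated risk versus true
risk, and the log learning rate of selected arms with visit markers.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .task import BLUE, OUTCOME_LABELS, RED
from .uncertainty import risk_entropy

__all__ = [
    "plot_estimation_uncertainty",
    "plot_no_jump_probability",
    "plot_risk_by_arm",
    "plot_learning_rate",
    "plot_trajectories",
]

_COLOR_MAP = {BLUE: "tab:blue", RED: "tab:red"}


def plot_estimation_uncertainty(diag: pd.DataFrame, metric: str = "entropy", ax=None):
    """Estimation uncertainty of the chosen arm per trial, coloured by arm colour."""
    ax = ax or plt.figure(figsize=(8, 3)).add_subplot()
    col = "est_ent_chosen" if metric == "entropy" else "est_var_chosen"
    ax.plot(diag["trial"], diag[col], lw=0.8, color="0.3")
    for color in (BLUE, RED):
        sub = diag[diag["color"] == color]
        ax.scatter(
            sub["trial"],
            np.full(len(sub), diag[col].min()),
            s=4,
            color=_COLOR_MAP[color],
            label=f"{color} chosen",
        )
    ax.set_xlabel("trial")
    ax.set_ylabel(f"estimation uncertainty ({metric})")
    ax.legend(loc="upper right", fontsize=8)
    return ax


def plot_no_jump_probability(diag: pd.DataFrame, session: pd.DataFrame | None = None, ax=None):
    """1 - pi per colour per trial, with markers at true jump trials if known."""
    ax = ax or plt.figure(figsize=(8, 3)).add_subplot()
    for color, col in ((BLUE, "pi_blue"), (RED, "pi_red")):
        ax.plot(
            diag["trial"], 1.0 - diag[col], lw=0.8, color=_COLOR_MAP[color],
            label=f"1 - pi ({color})",
        )
    if session is not None and "jump_blue" in session.columns:
        for color, col in ((BLUE, "jump_blue"), (RED, "jump_red")):
            jumps = session.loc[session[col] == 1, "trial"]
            ax.scatter(
                jumps, np.full(len(jumps), 1.02), marker="v", s=12,
                color=_COLOR_MAP[color],
            )
    ax.set_xlabel("trial")
    ax.set_ylabel("unexpected uncertainty")
    ax.legend(loc="upper right", fontsize=8)
    return ax


def plot_risk_by_arm(diag: pd.DataFrame, session: pd.DataFrame, ax=None):
    """Mean estimated risk per arm versus mean true risk (needs latent probs)."""
    if f"p0_{OUTCOME_LABELS[0]}" not in session.columns:
        warnings.warn(
            "session lacks latent probability columns; risk comparison skipped",
            UserWarning,
        )
        return None
    ax = ax or plt.figure(figsize=(6, 3)).add_subplot()
    est = [diag[f"risk_{j}"].mean() for j in range(6)]
    true = []
    for j in range(6):
        p = session[[f"p{j}_{lab}" for lab in OUTCOME_LABELS]].to_numpy()
        true.append(np.mean([risk_entropy(row) for row in p]))
    x = np.arange(6)
    ax.bar(x - 0.2, est, width=0.4, label="estimated", color="0.4")
    ax.bar(x + 0.2, true, width=0.4, label="true", color="0.7")
    ax.set_xticks(x, [f"arm {j}" for j in x])
    ax.set_ylabel("mean outcome entropy (nats)")
    ax.legend(fontsize=8)
    return ax


def plot_learning_rate(diag: pd.DataFrame, arms=(0, 3), ax=None):
    """log learning rate of selected arms per trial, visits marked with crosses."""
    ax = ax or plt.figure(figsize=(8, 3)).add_subplot()
    for j in arms:
        line, = ax.plot(diag["trial"], np.log(diag[f"eta_{j}"]), lw=0.8, label=f"arm {j}")
        visits = diag.loc[diag["arm"] == j, "trial"]
        ax.scatter(
            visits, np.full(len(visits), np.log(diag[f"eta_{j}"]).min() - 0.1),
            marker="x", s=10, color=line.get_color(),
        )
    ax.set_xlabel("trial")
    ax.set_ylabel("log learning rate")
    ax.legend(fontsize=8)
    return ax


def plot_trajectories(
    diag: pd.DataFrame,
    session: pd.DataFrame | None = None,
    out_dir: str | Path = ".",
    prefix: str = "session",
) -> dict[str, Path]:
    """Write the four diagnostic figures as PNGs; returns name -> path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _save(name, ax):
        if ax is None:
            return
        path = out / f"{prefix}_{name}.png"
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
        paths[name] = path

    _save("estimation_uncertainty", plot_estimation_uncertainty(diag))
    _save("no_jump_probability", plot_no_jump_probability(diag, session))
    if session is not None:
        _save("risk_by_arm", plot_risk_by_arm(diag, session))
    _save("learning_rate", plot_learning_rate(diag))
    return paths
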