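"""Matplotlib views of the standard experiments.

Thin plotting helpers over the experiment results: length-distribution
snapshots over time, stationary distributions across parameter values, and
sweep summaries (mean, variance, CV^2).  All functions return the figure so
callers can further customize or save it.
"""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .distributions import LengthDistribution
from .params import SUBUNITS_PER_MICRON


def _um(x: np.ndarray) -> np.ndarray:
    return np.asarray(x) / SUBUNITS_PER_MICRON


def plot_distributions(
    dists: Sequence[LengthDistribution],
    labels: Sequence[str],
    title: str = "",
    smooth_bins: int = 60,
):
    """Overlay length distributions (density per micron, coarse-binned)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for dist, label in zip(dists, labels):
        edges = np.linspace(0, dist.l_max + 1, smooth_bins + 1)
        mass, _ = np.histogram(dist.support, bins=edges, weights=dist.p)
        centers = 0.5 * (edges[1:] + edges[:-1])
        width_um = (edges[1] - edges[0]) / SUBUNITS_PER_MICRON
        ax.plot(_um(centers), mass / width_um, label=label)
    ax.set_xlabel("cable length (um)")
    ax.set_ylabel("probability density (1/um)")
    ax.legend(frameon=False)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    return fig


def plot_trajectory(traj, title: str = ""):
    """Cable length versus time for one stochastic realization."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.step(traj.times, _um(traj.lengths), where="post", lw=0.8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("cable length (um)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    return fig


def plot_sweep(df: pd.DataFrame, x: str, title: str = ""):
    """Mean (with analytic overlay), variance and CV^2 versus a swept rate."""
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    axes[0].errorbar(df[x], _um(df["ssa_mean"]), yerr=3 * _um(df["ssa_mean_se"]),
                     fmt="o", ms=3, label="simulation")
    axes[0].plot(df[x], _um(df["analytic_mean"]), "k-", label="rate balance")
    axes[0].set_ylabel("mean length (um)")
    axes[0].legend(frameon=False)
    axes[1].errorbar(df[x], df["ssa_variance"], yerr=3 * df["ssa_variance_se"],
                     fmt="o", ms=3)
    axes[1].set_ylabel("variance (subunits$^2$)")
    axes[2].errorbar(df[x], df["ssa_cv2"], yerr=3 * df["ssa_cv2_se"],
                     fmt="o", ms=3)
    axes[2].set_ylabel("CV$^2$")
    for ax in axes:
        ax.set_xlabel(x)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    return fig
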