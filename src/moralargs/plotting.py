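"""Figure-style summaries: trajectory panels, advantage histogram, and
change-rate scatter plots.  All functions return the matplotlib Axes and
accept an existing Axes for composition."""

from __future__ import annotations

from typing import Mapping

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_trajectories(results, ax=None, ci: bool = True):
    """Replicate-mean prevalence of the advantaged opinion per
    (ideology x frequency class) cell over time."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    t = np.arange(results.prevalence.shape[1])
    styles = {"liberal": "-", "conservative": "--"}
    for k, (ideo, cls) in enumerate(results.cells):
        traj = results.prevalence[k]
        mean = traj.mean(axis=1)
        ax.plot(t, mean, styles.get(ideo, "-"), label=f"{ideo} / {cls}")
        if ci and traj.shape[1] > 1:
            se = traj.std(axis=1, ddof=1) / np.sqrt(traj.shape[1])
            ax.fill_between(t, mean - 2 * se, mean + 2 * se, alpha=0.15)
    ax.set_xlabel("time step")
    ax.set_ylabel("prevalence of advantaged opinion")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    return ax


def plot_advantage_histogram(estimates: pd.DataFrame, prevalences=None, ax=None,
                             bins=15):
    """Histogram of item advantages; when group prevalences are supplied
    the liberal-leaning share of each bar is shaded."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    adv = estimates["advantage"].to_numpy(dtype=float)
    if prevalences is None:
        ax.hist(adv, bins=bins, color="0.3")
    else:
        lean = prevalences.set_index("item_id")
        lib = [
            lean.loc[i, "prev_liberal"] > lean.loc[i, "prev_conservative"]
            for i in estimates["item_id"]
        ]
        lib = np.asarray(lib)
        ax.hist(
            [adv[lib], adv[~lib]],
            bins=bins,
            stacked=True,
            color=["0.6", "0.1"],
            label=["more common among liberals", "other"],
        )
        ax.legend(fontsize=8)
    ax.set_xlabel("HVFL argument advantage")
    ax.set_ylabel("number of items")
    return ax


def plot_change_vs_advantage(
    advantages: Mapping[object, float], rates: pd.DataFrame, ax=None
):
    """Scatter of per-item change rate (log-odds/decade) on advantage with
    a least-squares line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    a = np.array([advantages[i] for i in rates["item_id"]], dtype=float)
    y = rates["slope"].to_numpy(dtype=float)
    ok = np.isfinite(a) & np.isfinite(y)
    a, y = a[ok], y[ok]
    ax.scatter(a, y, s=18, color="0.2")
    if len(a) >= 2 and a.std() > 0:
        b, a0 = np.polyfit(a, y, 1)
        xs = np.linspace(a.min(), a.max(), 20)
        ax.plot(xs, a0 + b * xs, color="0.5")
    ax.set_xlabel("HVFL argument advantage")
    ax.set_ylabel("opinion change (log odds / decade)")
    return ax
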