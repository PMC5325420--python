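"""Plot helpers mirroring the standard report figures.

All functions require matplotlib (the ``plot`` extra) and accept an
optional Axes; they return the Figure so callers can save it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import Trajectory
from .screens import ScreenResult


def _mpl():
    try:
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "plotting requires matplotlib; install crosstalksim[plot]"
        ) from exc
    return plt


def plot_trajectory(traj: Trajectory, ax=None):
    """Activation fractions of all five species over time."""
    plt = _mpl()
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    for name in ("A", "B", "C", "D", "O"):
        ax.plot(traj.times, traj.species(name), label=name)
    ax.set_xlabel("time")
    ax.set_ylabel("active (frac)")
    ax.set_ylim(-0.02, 1.0)
    ax.legend(frameon=False, ncol=5, fontsize=8)
    meta = traj.metadata
    ax.set_title(
        f"module {meta.get('module_id', '?')}  "
        f"{meta.get('regimen', '')}  {meta.get('stimulus', '')}",
        fontsize=9,
    )
    return ax.figure


def plot_rde_bars(result: ScreenResult, ax=None):
    """Bar chart of relative drug efficacy per module (single-drug screen)."""
    plt = _mpl()
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    records = result.records
    scale = records["crosstalk_scale"].iloc[0]
    sub = records[records["crosstalk_scale"] == scale]
    colors = ["#b2182b" if r < 0 else "#2166ac" for r in sub["rde"]]
    ax.bar(sub["module_id"].astype(str), sub["rde"], color=colors)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xlabel("module")
    ax.set_ylabel("relative drug efficacy")
    return ax.figure


def plot_ci_heatmap(result: ScreenResult, ax=None):
    """Heatmap of Bliss CI over (module, partner) for a combination screen."""
    plt = _mpl()
    if ax is None:
        _, ax = plt.subplots(figsize=(4.2, 4.2))
    piv = result.records.pivot(index="module_id", columns="partner",
                               values="ci")
    vmax = float(np.nanmax(np.abs(piv.values))) or 1.0
    im = ax.imshow(piv.values, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(piv.shape[1]), piv.columns)
    ax.set_yticks(range(piv.shape[0]), piv.index)
    ax.set_xlabel("partner target")
    ax.set_ylabel("module")
    ax.figure.colorbar(im, ax=ax, label="Bliss CI")
    return ax.figure


def plot_strength_curves(result: ScreenResult, ax=None):
    """RDE versus crosstalk scale, one curve per module."""
    plt = _mpl()
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.4))
    for m, grp in result.records.groupby("module_id"):
        grp = grp.sort_values("crosstalk_scale")
        ax.plot(grp["crosstalk_scale"], grp["rde"], marker="o",
                ms=3, label=f"M{m}")
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xscale("log")
    ax.set_xlabel("crosstalk scale")
    ax.set_ylabel("relative drug efficacy")
    ax.legend(frameon=False, fontsize=7, ncol=3)
    return ax.figure


_SCREEN_PLOTS = {
    "single_drug": plot_rde_bars,
    "combination": plot_ci_heatmap,
    "strength_scan": plot_strength_curves,
    "stimulus_scan": plot_rde_bars,
}


def save_screen_plot(result: ScreenResult, out_dir: str | Path) -> Path:
    """Render the default figure for a screen kind into ``out_dir``."""
    fig = _SCREEN_PLOTS[result.kind](result)
    path = Path(out_dir) / f"{result.kind}.png"
    fig.savefig(path, dpi=150, bbox_inches="tight")
    return path
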