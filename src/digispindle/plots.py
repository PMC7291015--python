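"""Static summary figures from the classification tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from matplotlib.figure import Figure

__all__ = ["plot_speed_histogram", "plot_zone_angle_histograms"]


def plot_speed_histogram(speed_bins: pd.DataFrame, path: str | Path) -> None:
    """Bar plot of trajectory counts per speed class (from speed_bins.csv)."""
    fig = Figure(figsize=(5, 3.2))
    ax = fig.add_subplot()
    centers = 0.5 * (speed_bins["lower_um_s"] + speed_bins["upper_um_s"])
    width = (speed_bins["upper_um_s"] - speed_bins["lower_um_s"]).iloc[0]
    ax.bar(centers, speed_bins["count"], width=0.9 * width, color="#2c7fb8")
    ax.set_xlabel("mean travel speed (µm/s)")
    ax.set_ylabel("trajectories")
    fig.tight_layout()
    fig.savefig(path, dpi=150)


def plot_zone_angle_histograms(zone_summary: pd.DataFrame,
                               path: str | Path) -> None:
    """Per-zone travel-angle histograms (from zone_summary.csv), 10° bins."""
    hist_cols = [c for c in zone_summary.columns if c.startswith("hist_")]
    edges = np.array(
        [float(c.split("_")[1]) for c in hist_cols] + [180.0]
    )
    zones = zone_summary["zone"].tolist()
    n = len(zones)
    ncols = min(5, max(n, 1))
    nrows = int(np.ceil(n / ncols)) if n else 1
    fig = Figure(figsize=(2.2 * ncols, 1.9 * nrows))
    axes = fig.subplots(nrows, ncols, squeeze=False)
    for ax in axes.ravel():
        ax.set_axis_off()
    for k, (_, row) in enumerate(zone_summary.iterrows()):
        ax = axes.ravel()[k]
        ax.set_axis_on()
        ax.bar(edges[:-1], row[hist_cols].to_numpy(dtype=float),
               width=9.0, align="edge", color="#31a354")
        ax.set_title(f"zone {row['zone']} (n={int(row['count'])})", fontsize=8)
        ax.set_xlim(0, 180)
        ax.set_xticks([0, 90, 180])
        ax.tick_params(labelsize=7)
    fig.supxlabel("travel angle vs spindle axis (°)", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
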