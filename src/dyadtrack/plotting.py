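"""Diagnostic plots for QC distributions and gaze statistics."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .behavior import GazeHistogram2D, head_to_head_distance, smooth_series
from .io import TrackTable


def plot_asymmetry_timeline(
    windows: pd.DataFrame, tracks: TrackTable | None = None, ax=None, smooth: int = 5
):
    """Windowed gaze asymmetry (and optionally head-to-head distance) vs time."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    t_min = windows["time_s"] / 60.0
    ax.plot(t_min, windows["A_gaze"], color="tab:blue", alpha=0.4, label="A_gaze")
    ax.plot(
        t_min,
        smooth_series(windows["A_gaze"].to_numpy(), smooth),
        color="tab:blue",
        lw=2,
        ls="--",
        label="A_gaze (smoothed)",
    )
    ax.set_xlabel("time (min)")
    ax.set_ylabel("gaze asymmetry")
    ax.set_ylim(0, 1)
    if tracks is not None:
        ax2 = ax.twinx()
        d = head_to_head_distance(tracks)
        fs = windows["window_len_frames"].iloc[0] / (
            windows["time_s"].diff().iloc[1] if len(windows) > 1 else 120.0
        )
        t = (tracks.frames - tracks.frames[0]) / fs / 60.0
        ax2.plot(t, d, color="tab:green", alpha=0.3, label="head-head distance")
        ax2.set_ylabel("distance (cm)")
    ax.legend(loc="upper left", fontsize=8)
    return ax


def plot_gaze_histogram(hist: GazeHistogram2D, ax=None):
    """2D gaze-angle histogram (fish 1 on x, fish 2 on y)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    extent = [hist.edges[0], hist.edges[-1], hist.edges[0], hist.edges[-1]]
    im = ax.imshow(
        hist.density.T, origin="lower", extent=extent, aspect="equal", cmap="viridis"
    )
    ax.set_xlabel(r"$\theta_{1\to 2}$ (deg)")
    ax.set_ylabel(r"$\theta_{2\to 1}$ (deg)")
    plt.colorbar(im, ax=ax, fraction=0.046)
    return ax


def plot_coverage(summary, ax=None):
    """Bar chart of full/empty frame fractions and per-flag removals."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    labels = ["full", "empty"] + sorted(summary.flag_counts)
    values = [summary.n_frames_full, summary.n_frames_empty] + [
        summary.flag_counts[k] for k in sorted(summary.flag_counts)
    ]
    ax.bar(np.arange(len(labels)), values)
    ax.set_xticks(np.arange(len(labels)), labels, rotation=45, ha="right", fontsize=8)
    ax.set_ylabel("frames")
    return ax
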