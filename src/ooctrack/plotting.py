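"""Publication-style figures for the pipeline outputs."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_trajectories(tracks, ax=None, tumor_tracks=()):
    """Trajectories in chip coordinates (origin bottom-left, y up)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for t in tracks:
        ax.plot(t.x, t.y, lw=0.8)
    for t in tumor_tracks:
        ax.plot(t.x.mean(), t.y.mean(), "ko", ms=8)
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    ax.set_aspect("equal")
    return ax


def plot_step_distributions(steps, axes=None):
    """Semi-log histograms of step length per axis and sign."""
    if axes is None:
        _, axes = plt.subplots(2, 2, figsize=(8, 6))
    panels = [
        ("dx > 0", steps.dx[steps.dx > 0]),
        ("dx < 0", -steps.dx[steps.dx < 0]),
        ("dy > 0", steps.dy[steps.dy > 0]),
        ("dy < 0", -steps.dy[steps.dy < 0]),
    ]
    for ax, (title, vals) in zip(axes.ravel(), panels):
        if len(vals):
            counts, edges = np.histogram(vals, bins=30)
            centers = 0.5 * (edges[:-1] + edges[1:])
            keep = counts > 0
            ax.semilogy(centers[keep], counts[keep], "o", ms=3)
        ax.set_title(title)
        ax.set_xlabel("|step| (um)")
    return axes


def plot_turning_polar(hist, ax=None):
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    centers = 0.5 * (hist.bin_edges[:-1] + hist.bin_edges[1:])
    width = np.diff(hist.bin_edges)
    ax.bar(centers, hist.frequencies, width=width, alpha=0.7)
    return ax


def plot_polar_profile(polar_track, range_estimate=None, ax=None):
    """r versus theta, frame by frame, with the detected basin entry."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(polar_track.theta, polar_track.r, ".-", ms=3, lw=0.5)
    if range_estimate is not None and range_estimate.detected:
        for k in range_estimate.breakpoints:
            ax.axhline(polar_track.r[k], color="r", ls="--", lw=0.8)
    ax.set_xlabel("theta (rad)")
    ax.set_ylabel("r (um)")
    return ax


def plot_eigen_series(series, ax=None):
    if ax is None:
        _, ax = plt.subplots()
    ax.errorbar(series["t"], series["lambda1"], yerr=series["se1"], fmt="o-", ms=3, label="lambda1")
    ax.errorbar(series["t"], series["lambda2"], yerr=series["se2"], fmt="s-", ms=3, label="lambda2")
    ax.axhline(0, color="k", lw=0.5)
    ax.invert_xaxis()  # t decreases toward contact
    ax.set_xlabel("t (steps before contact)")
    ax.set_ylabel("Lyapunov coefficient (1/min)")
    ax.legend()
    return ax


def plot_landscape(surface, x_grid, y_grid, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    cs = ax.contourf(x_grid, y_grid, surface, levels=20, cmap="viridis")
    plt.colorbar(cs, ax=ax, label="relative potential")
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    ax.set_aspect("equal")
    return ax
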