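"""Random-walk migration descriptors.

From an ensemble of tracks we build per-time-lapse step samples
``(dx, dy, dtheta)`` and characterize the walk:

* per-axis, per-sign step-length distributions, fitted as exponential vs
  half-Gaussian on a semi-log histogram (the two shapes discriminate biased
  from unbiased motion along each direction);
* a motion-regime classifier mapping the four branch models onto the three
  chemotaxis phenotypes (strong drift in both axes, drift along x only,
  isotropic);
* polar histograms of the turning angle with circular statistics (a peaked
  histogram means persistent, focused motion);
* velocity histograms at a fixed number of steps before tumor contact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import Track


@dataclass
class StepSample:
    """Displacements over one time lapse.  ``dtheta`` (turning angle, signed
    change of heading between consecutive displacement vectors) is NaN where
    undefined (first step of a segment, or zero-length displacement)."""

    dx: np.ndarray
    dy: np.ndarray
    dtheta: np.ndarray
    dt: float = 2.0
    n_skipped_dtheta: int = 0


@dataclass
class BranchFit:
    """Semi-log fit of one signed step-length branch."""

    axis: str
    sign: str
    model: str  # 'exponential' | 'gaussian' | 'indeterminate'
    scale: float
    scale_se: float
    r2_exponential: float
    r2_gaussian: float
    n_points: int
    tail_truncation: int

    @property
    def r2(self):
        return {"exponential": self.r2_exponential, "gaussian": self.r2_gaussian}.get(
            self.model, float("nan")
        )


@dataclass
class MotionClass:
    label: str  # drift_xy | drift_x_only | isotropic | indeterminate
    branch_models: dict


@dataclass
class TurningAngleHistogram:
    bin_edges: np.ndarray
    frequencies: np.ndarray
    circular_mean: float
    resultant_length: float
    peak_frequency: float


def compute_steps(track: Track, dt=2.0, max_gap=1) -> StepSample:
    """Per-lapse displacements and turning angles for one track.

    Steps across closed gaps (frame difference > ``max_gap``) are excluded.
    The turning angle needs two consecutive valid steps; pairs involving a
    zero-length displacement are skipped and counted.
    """
    if len(track) < 3:
        raise ValueError("track must have at least 3 points")
    df = np.diff(track.frames)
    valid = df <= max_gap
    dx = np.diff(track.x)[valid]
    dy = np.diff(track.y)[valid]

    # headings of consecutive valid step pairs (both steps gap-free and the
    # pair itself contiguous in the original sequence)
    dx_all, dy_all = np.diff(track.x), np.diff(track.y)
    dtheta = []
    skipped = 0
    for i in range(len(df) - 1):
        if not (valid[i] and valid[i + 1]):
            continue
        v1 = (dx_all[i], dy_all[i])
        v2 = (dx_all[i + 1], dy_all[i + 1])
        if np.hypot(*v1) == 0 or np.hypot(*v2) == 0:
            skipped += 1
            continue
        ang = np.arctan2(v2[1], v2[0]) - np.arctan2(v1[1], v1[0])
        dtheta.append(wrap_angle(ang))
    return StepSample(dx, dy, np.asarray(dtheta, dtype=float), dt, skipped)


def pool_steps(tracks, dt=2.0, max_gap=1) -> StepSample:
    """Pool step samples over an ensemble of tracks."""
    parts = [compute_steps(t, dt, max_gap) for t in tracks if len(t) >= 3]
    if not parts:
        raise ValueError("no track long enough for step statistics")
    return StepSample(
        np.concatenate([p.dx for p in parts]),
        np.concatenate([p.dy for p in parts]),
        np.concatenate([p.dtheta for p in parts]),
        dt,
        sum(p.n_skipped_dtheta for p in parts),
    )


def wrap_angle(a):
    """Wrap an angle (or array) to (-pi, pi]."""
    out = -((-np.asarray(a) + np.pi) % (2 * np.pi) - np.pi)
    return out if out.ndim else float(out)


def _fd_bins(x):
    """Freedman-Diaconis bin count, clipped to a sane range."""
    x = np.asarray(x)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    if iqr <= 0:
        return 10
    width = 2 * iqr / len(x) ** (1 / 3)
    return int(np.clip(np.ceil((x.max() - x.min()) / width), 5, 200))


def fit_branch(magnitudes, axis="x", sign="+", min_samples=50, min_bin_count=5,
               tie_threshold=0.01) -> BranchFit:
    """Fit one signed step-length branch as exponential vs half-Gaussian.

    Histogram the magnitudes (Freedman-Diaconis bins), drop tail bins with
    fewer than ``min_bin_count`` counts, then fit the log-frequency linearly
    in |step| (exponential) and in step^2 (Gaussian).  The model with the
    larger R^2 wins; a difference below ``tie_threshold`` is indeterminate.
    The reported scale is the maximum-likelihood one for the chosen model
    (mean for exponential, sqrt(mean of squares) for half-Gaussian).
    """
    mag = np.asarray(magnitudes, dtype=float)
    mag = mag[np.isfinite(mag) & (mag > 0)]
    if len(mag) < min_samples:
        raise ValueError(f"branch {axis}{sign}: need >= {min_samples} samples, got {len(mag)}")

    counts, edges = np.histogram(mag, bins=_fd_bins(mag))
    centers = 0.5 * (edges[:-1] + edges[1:])
    # neglect the sparse tail: strip trailing bins below the count floor
    last = len(counts)
    while last > 0 and counts[last - 1] < min_bin_count:
        last -= 1
    truncated = len(counts) - last
    keep = (counts[:last] >= min_bin_count)
    c, ctr = counts[:last][keep], centers[:last][keep]
    if len(c) < 3:
        raise ValueError(f"branch {axis}{sign}: too few populated histogram bins")

    logf = np.log(c.astype(float))
    r2_exp = _linear_r2(ctr, logf)
    r2_gau = _linear_r2(ctr**2, logf)

    if abs(r2_exp - r2_gau) < tie_threshold:
        model = "indeterminate"
    elif r2_exp > r2_gau:
        model = "exponential"
    else:
        model = "gaussian"

    n = len(mag)
    if model == "gaussian":
        scale = float(np.sqrt(np.mean(mag**2)))  # half-normal sigma MLE
        scale_se = scale / np.sqrt(2 * n)
    else:
        scale = float(np.mean(mag))  # exponential scale MLE
        scale_se = scale / np.sqrt(n)
    return BranchFit(axis, sign, model, scale, scale_se, r2_exp, r2_gau, n, truncated)


def _linear_r2(x, y):
    X = np.column_stack([x, np.ones_like(x)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sstot = np.sum((y - y.mean()) ** 2)
    if sstot == 0:
        return 1.0
    return float(1 - np.sum(resid**2) / sstot)


def fit_all_branches(steps: StepSample, **kw):
    """Fit the four (axis, sign) branches of a pooled step sample."""
    fits = {}
    for axis, vals in (("x", steps.dx), ("y", steps.dy)):
        for sign, sel in (("+", vals[vals > 0]), ("-", -vals[vals < 0])):
            fits[(axis, sign)] = fit_branch(sel, axis, sign, **kw)
    return fits


def classify_motion(fits) -> MotionClass:
    """Map the four branch models onto a migration phenotype.

    A Gaussian branch marks the drift side of a drifted axis.  Exactly one
    Gaussian branch per axis on both axes => ``drift_xy``; on the x axis
    only => ``drift_x_only``; all four exponential => ``isotropic``; any
    other pattern => ``indeterminate``.
    """
    table = {f"{ax}{sg}": f.model for (ax, sg), f in fits.items()}
    if any(m == "indeterminate" for m in table.values()):
        return MotionClass("indeterminate", table)

    def n_gauss(axis):
        return sum(1 for (ax, _), f in fits.items() if ax == axis and f.model == "gaussian")

    gx, gy = n_gauss("x"), n_gauss("y")
    if gx == 1 and gy == 1:
        return MotionClass("drift_xy", table)
    if gx == 1 and gy == 0:
        return MotionClass("drift_x_only", table)
    if gx == 0 and gy == 0:
        return MotionClass("isotropic", table)
    return MotionClass("indeterminate", table)


def turning_histogram(dtheta, n_bins=24) -> TurningAngleHistogram:
    """Normalized circular histogram of turning angles with circular stats."""
    if n_bins % 2:
        raise ValueError("n_bins must be even")
    a = np.asarray(dtheta, dtype=float)
    a = a[np.isfinite(a)]
    if len(a) == 0:
        raise ValueError("no turning-angle samples")
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    counts, _ = np.histogram(a, bins=edges)
    freqs = counts / counts.sum()
    C, S = np.mean(np.cos(a)), np.mean(np.sin(a))
    return TurningAngleHistogram(
        bin_edges=edges,
        frequencies=freqs,
        circular_mean=float(np.arctan2(S, C)),
        resultant_length=float(np.hypot(C, S)),
        peak_frequency=float(freqs.max()),
    )


def velocity_histograms(polar_tracks, t_index, n_bins=20):
    """Histograms of speed and velocity components ``t_index`` steps before contact.

    ``polar_tracks`` carry a backward time index (t = 0 at closest approach
    to the tumor cell, increasing backward); at the requested index the
    magnitude |v|, Cartesian components (vx, vy) and polar components
    (vr, vtheta) are collected over all tracks long enough, and histogrammed
    with each histogram rescaled so its maximum bin equals 1.
    """
    vals = {"v": [], "vx": [], "vy": [], "vr": [], "vtheta": []}
    for pt in polar_tracks:
        idx = np.nonzero(pt.t == t_index)[0]
        if len(idx) == 0:
            continue
        i = int(idx[0])
        vals["vr"].append(pt.v_r[i])
        vals["vtheta"].append(pt.v_theta[i])
        vx, vy = pt.v_x[i], pt.v_y[i]
        vals["vx"].append(vx)
        vals["vy"].append(vy)
        vals["v"].append(np.hypot(vx, vy))
    if not vals["v"]:
        raise ValueError(f"no polar track reaches backward index t={t_index}")

    out = {}
    for key, v in vals.items():
        counts, edges = np.histogram(np.asarray(v), bins=n_bins)
        peak = counts.max()
        out[key] = (edges, counts / peak if peak > 0 else counts.astype(float))
    return out
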