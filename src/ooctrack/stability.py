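"""Lyapunov-stability analysis of immune-cell / tumor-cell encounters.

Each near-stationary tumor cell (TC) is treated as a candidate attractor of
the immune-cell (PBMC) dynamics.  For every PBMC approaching a TC we:

1. rebase the trajectory to polar coordinates ``(r, theta)`` about the TC's
   time-averaged position, setting the backward clock t = 0 at the
   trajectory point closest to the TC (the empirical fixed point, where the
   velocity is smallest);
2. locate the *interaction range* — the radius at which the cell starts to
   fall toward the attractor — by an abrupt change of slope in the polar
   plot r(theta), found by segmented least-squares with BIC model selection;
3. select the *linearization range*: the largest window of consecutive
   time points around t = 0 on which both polar velocities fit an affine
   function of ``(r - r0, theta - theta0)`` with R^2 at or above a
   threshold (0.95 by default);
4. estimate the 2x2 Jacobian of the linearized dynamics by least squares
   and classify the encounter from the signs of its eigenvalues (the
   Lyapunov coefficients): both negative => stable, both positive =>
   unstable, mixed => metastable (saddle);
5. re-estimate the spectrum on growing sub-windows to obtain the time
   evolution of the Lyapunov coefficients, a robustness check on the final
   classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import Track


@dataclass
class StabilityConfig:
    """Tunables of the encounter analysis (lengths in micrometres, times in
    minutes)."""

    dt: float = 2.0
    pbmc_diameter: float = 9.0
    tc_diameter: float = 20.0
    r2_min: float = 0.95
    min_window_points: int = 5
    stationarity_tol: float = 10.0
    default_interaction_range: float = 50.0
    bic_margin: float = 10.0
    max_candidate_radius: float = 200.0


@dataclass
class TumorAttractor:
    """A tumor cell considered as a candidate fixed point."""

    tc_id: int
    x0: float
    y0: float
    tc_diameter: float
    pbmc_mean_diameter: float
    interaction_range: float | None = None
    basin_members: list = field(default_factory=list)

    @property
    def physical_interaction_range(self) -> float:
        """Contact radius: sum of the mean TC and PBMC diameters."""
        return self.tc_diameter + self.pbmc_mean_diameter


@dataclass
class PolarTrack:
    """A PBMC trajectory rebased about a tumor-cell attractor.

    ``t`` counts time-lapse steps backward from contact: t = 0 at the
    trajectory point closest to the TC, positive before it, negative after.
    ``theta`` is unwrapped; velocities are central finite differences
    (one-sided at the ends).
    """

    track_id: int
    r: np.ndarray
    theta: np.ndarray
    v_r: np.ndarray
    v_theta: np.ndarray
    v_x: np.ndarray
    v_y: np.ndarray
    t: np.ndarray
    frames: np.ndarray
    dt: float

    @property
    def i0(self) -> int:
        """Index of the closest-approach (t = 0) point."""
        return int(np.nonzero(self.t == 0)[0][0])


@dataclass
class JacobianEstimate:
    A: np.ndarray
    A_se: np.ndarray
    r2_vr: float
    r2_vtheta: float
    eigenvalues: np.ndarray  # ordered by real part, lambda1 <= lambda2
    eigen_se: np.ndarray
    complex_flag: bool
    n_points: int


@dataclass
class LinearizationWindow:
    lo: int
    hi: int
    i0: int
    r0: float
    theta0: float
    r: np.ndarray
    theta: np.ndarray
    v_r: np.ndarray
    v_theta: np.ndarray
    r2_vr: float
    r2_vtheta: float

    @property
    def linearization_range(self) -> float:
        return float(np.max(self.r))

    @property
    def n_points(self) -> int:
        return self.hi - self.lo + 1


@dataclass
class RangeEstimate:
    detected: bool
    range_um: float | None
    breakpoints: tuple
    n_segments: int
    bic_single: float
    bic_best: float


@dataclass
class StabilityResult:
    pbmc_id: int
    tc_id: int
    classification: str
    jacobian: JacobianEstimate | None
    eigen_series: pd.DataFrame | None
    interaction_range: float | None
    linearization_range: float | None
    window: LinearizationWindow | None


def build_attractor(tumor_track: Track, pbmc_tracks=(), config=None, tc_id=None) -> TumorAttractor:
    """Time-average a tumor track into a candidate fixed point.

    Warns when the TC wanders beyond the stationarity tolerance (the fixed
    point assumption is then questionable).
    """
    config = config or StabilityConfig()
    if len(tumor_track) == 0:
        raise ValueError("tumor track is empty")
    x0, y0 = float(tumor_track.x.mean()), float(tumor_track.y.mean())
    disp = np.hypot(tumor_track.x - x0, tumor_track.y - y0)
    if disp.max() > config.stationarity_tol:
        warnings.warn(
            f"tumor track {tumor_track.track_id} moves {disp.max():.1f} um from its mean; "
            "fixed-point assumption may be poor"
        )
    return TumorAttractor(
        tc_id=tc_id if tc_id is not None else tumor_track.track_id,
        x0=x0,
        y0=y0,
        tc_diameter=config.tc_diameter,
        pbmc_mean_diameter=config.pbmc_diameter,
    )


def rebase_polar(pbmc_track: Track, attractor: TumorAttractor, dt=2.0) -> PolarTrack:
    """Express a PBMC track in polar coordinates about the attractor.

    theta is unwrapped over time; t = 0 is assigned to the point of minimal
    r (the relaxed fixed point of the noisy dynamics), with t increasing
    backward in time.
    """
    if len(pbmc_track) == 0:
        raise ValueError("pbmc track is empty")
    rel_x = pbmc_track.x - attractor.x0
    rel_y = pbmc_track.y - attractor.y0
    r = np.hypot(rel_x, rel_y)
    theta = np.unwrap(np.arctan2(rel_y, rel_x))
    time = pbmc_track.frames * dt
    i0 = int(np.argmin(r))
    t = i0 - np.arange(len(r))
    if len(r) > 1:
        v_r = np.gradient(r, time)
        v_theta = np.gradient(theta, time)
        v_x = np.gradient(pbmc_track.x, time)
        v_y = np.gradient(pbmc_track.y, time)
    else:
        v_r = v_theta = v_x = v_y = np.zeros(1)
    return PolarTrack(
        pbmc_track.track_id, r, theta, v_r, v_theta, v_x, v_y, t, pbmc_track.frames.copy(), dt
    )


class _SegmentSSE:
    """O(1) residual sum of squares of line fits r ~ theta on index ranges,
    via prefix sums."""

    def __init__(self, theta, r):
        z = np.zeros(1)
        self.cx = np.concatenate([z, np.cumsum(theta)])
        self.cy = np.concatenate([z, np.cumsum(r)])
        self.cxx = np.concatenate([z, np.cumsum(theta * theta)])
        self.cyy = np.concatenate([z, np.cumsum(r * r)])
        self.cxy = np.concatenate([z, np.cumsum(theta * r)])

    def __call__(self, i, j):
        n = j - i + 1
        sx = self.cx[j + 1] - self.cx[i]
        sy = self.cy[j + 1] - self.cy[i]
        sxx = self.cxx[j + 1] - self.cxx[i] - sx * sx / n
        syy = self.cyy[j + 1] - self.cyy[i] - sy * sy / n
        sxy = self.cxy[j + 1] - self.cxy[i] - sx * sy / n
        if sxx <= 1e-300:
            return float(max(syy, 0.0))
        return float(max(syy - sxy * sxy / sxx, 0.0))


def _bic(sse, n, k):
    return n * np.log(max(sse, 1e-12) / n) + k * np.log(n)


def estimate_interaction_range(polar_track: PolarTrack, min_points=12,
                               bic_margin=10.0, try_three=True) -> RangeEstimate:
    """Locate the basin entry from the abrupt change of slope dr/dtheta.

    The time-ordered polar profile r(theta) is fitted with one, two and
    (optionally) three least-squares line segments split at candidate time
    indices; a changepoint is accepted when the segmented model beats the
    single line by ``bic_margin`` in BIC.  The interaction range is r at
    the first breakpoint (basin entry).  A three-segment model (approach /
    engaged / leave) supersedes the two-segment one when it lowers BIC by
    the same margin, covering encounters that also leave the attractor.
    """
    th, r = polar_track.theta, polar_track.r
    n = len(r)
    if n < min_points:
        raise ValueError(f"need >= {min_points} points, got {n}")
    seg = _SegmentSSE(th, r)

    sse1 = seg(0, n - 1)
    bic1 = _bic(sse1, n, 3)

    best2 = None
    for k in range(2, n - 2):
        sse = seg(0, k) + seg(k, n - 1)
        if best2 is None or sse < best2[0]:
            best2 = (sse, k)
    sse2, k2 = best2
    bic2 = _bic(sse2, n, 6)

    best = None
    if bic2 < bic1 - bic_margin:
        best = RangeEstimate(True, float(r[k2]), (k2,), 2, bic1, bic2)
        if try_three and n >= 9:
            best3 = None
            for ka in range(2, n - 5):
                sse_a = seg(0, ka)
                for kb in range(ka + 3, n - 2):
                    sse = sse_a + seg(ka, kb) + seg(kb, n - 1)
                    if best3 is None or sse < best3[0]:
                        best3 = (sse, ka, kb)
            if best3 is not None:
                sse3, ka, kb = best3
                bic3 = _bic(sse3, n, 9)
                if bic3 < bic2 - bic_margin:
                    best = RangeEstimate(True, float(r[ka]), (ka, kb), 3, bic1, bic3)
    if best is None:
        best = RangeEstimate(False, None, (), 1, bic1, bic2)
    return best


def _rowfit_r2(dr, dth, v):
    """Affine least squares v ~ 1 + dr + dth; returns (slopes, R^2, slope cov).

    The intercept absorbs the residual drift at the empirical fixed point
    (the closest-approach point need not carry exactly zero velocity), so
    the slope estimates — the Jacobian row — are invariant to that offset.
    """
    X = np.column_stack([np.ones_like(dr), dr, dth])
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    resid = v - X @ beta
    sstot = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 if sstot == 0 else float(1 - resid @ resid / sstot)
    n, p = X.shape
    dof = max(n - p, 1)
    s2 = float(resid @ resid) / dof
    try:
        cov = s2 * np.linalg.inv(X.T @ X)[1:, 1:]
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.nan)
    return beta[1:], r2, cov


def _window_r2(pt: PolarTrack, lo, hi):
    """Both row-fit R^2 on the inclusive window [lo, hi] about the t=0 point."""
    i0 = pt.i0
    dr = pt.r[lo : hi + 1] - pt.r[i0]
    dth = pt.theta[lo : hi + 1] - pt.theta[i0]
    _, r2_r, _ = _rowfit_r2(dr, dth, pt.v_r[lo : hi + 1])
    _, r2_t, _ = _rowfit_r2(dr, dth, pt.v_theta[lo : hi + 1])
    return r2_r, r2_t


def select_linearization_window(polar_track: PolarTrack, interaction_range,
                                r2_min=0.95, min_points=5) -> LinearizationWindow | None:
    """Largest time-contiguous window about t = 0 with a good linear fit.

    Only points inside the interaction range are eligible (the maximal
    contiguous run containing the closest-approach point).  The window is
    grown greedily one point at a time, choosing at each step the side
    (earlier or later in time) whose inclusion keeps the minimum of the two
    row-fit R^2 highest; the growth path does not depend on ``r2_min``, and
    the selected window is the largest one along the path for which both
    R^2 values reach the threshold.  Returns ``None`` when even the minimal
    window fails (encounter indeterminate).
    """
    pt = polar_track
    i0 = pt.i0
    n = len(pt.r)
    if pt.r[i0] > interaction_range:
        return None
    lo = i0
    while lo > 0 and pt.r[lo - 1] <= interaction_range:
        lo -= 1
    hi = i0
    while hi < n - 1 and pt.r[hi + 1] <= interaction_range:
        hi += 1
    if hi - lo + 1 < min_points:
        return None

    # threshold-independent greedy growth path from the t=0 point outward
    cur_lo, cur_hi = i0, i0
    path = []
    while cur_lo > lo or cur_hi < hi:
        cands = []
        if cur_lo > lo:
            cands.append((cur_lo - 1, cur_hi, 0))
        if cur_hi < hi:
            cands.append((cur_lo, cur_hi + 1, 1))
        scored = []
        for c_lo, c_hi, side in cands:
            if c_hi - c_lo + 1 >= 3:
                r2s = _window_r2(pt, c_lo, c_hi)
                score = min(r2s)
            else:
                r2s, score = (1.0, 1.0), 1.0
            scored.append((score, -1 + side, c_lo, c_hi, r2s))
        # prefer higher score; tie -> extend backward in time (side 0)
        scored.sort(key=lambda s: (-s[0], s[1]))
        _, _, cur_lo, cur_hi, r2s = scored[0]
        path.append((cur_lo, cur_hi, r2s))

    best = None
    for c_lo, c_hi, r2s in path:
        if c_hi - c_lo + 1 < min_points:
            continue
        if r2s[0] >= r2_min and r2s[1] >= r2_min:
            best = (c_lo, c_hi, r2s)
    if best is None:
        return None
    b_lo, b_hi, (r2_r, r2_t) = best
    return LinearizationWindow(
        lo=b_lo,
        hi=b_hi,
        i0=i0,
        r0=float(pt.r[i0]),
        theta0=float(pt.theta[i0]),
        r=pt.r[b_lo : b_hi + 1].copy(),
        theta=pt.theta[b_lo : b_hi + 1].copy(),
        v_r=pt.v_r[b_lo : b_hi + 1].copy(),
        v_theta=pt.v_theta[b_lo : b_hi + 1].copy(),
        r2_vr=r2_r,
        r2_vtheta=r2_t,
    )


def _eigen_with_se(A, cov_row1, cov_row2):
    """Eigenvalues of a fitted 2x2 matrix with first-order error propagation.

    The two regression rows are independent, so the covariance is block
    diagonal in ((a11, a12), (a21, a22)).  For a complex pair the standard
    error of the common real part (trace/2) is reported for both.
    """
    a11, a12 = A[0]
    a21, a22 = A[1]
    tr, det = a11 + a22, a11 * a22 - a12 * a21
    disc = tr * tr - 4 * det
    var_tr_half = 0.25 * (cov_row1[0, 0] + cov_row2[1, 1])
    if disc < 0:
        lam = np.sort_complex(np.linalg.eigvals(A))
        se = np.full(2, np.sqrt(var_tr_half))
        order = np.argsort(lam.real)
        return lam[order], se[order], True
    s = np.sqrt(disc)
    lams, ses = [], []
    for pm in (-1.0, +1.0):
        if s > 1e-12:
            g11 = 0.5 * (1 + pm * (a11 - a22) / s)
            g22 = 0.5 * (1 + pm * (a22 - a11) / s)
            g12 = pm * a21 / s
            g21 = pm * a12 / s
            g1 = np.array([g11, g12])
            g2 = np.array([g21, g22])
            var = float(g1 @ cov_row1 @ g1 + g2 @ cov_row2 @ g2)
        else:
            var = var_tr_half
        lams.append((tr + pm * s) / 2)
        ses.append(np.sqrt(max(var, 0.0)))
    lams, ses = np.array(lams), np.array(ses)
    order = np.argsort(lams)
    return lams[order].astype(complex), ses[order], False


def estimate_jacobian(window: LinearizationWindow) -> JacobianEstimate:
    """Least-squares Jacobian of the linearized polar dynamics.

    Fits ``v_r ~ c1 + a11 (r - r0) + a12 (theta - theta0)`` and
    ``v_theta ~ c2 + a21 (r - r0) + a22 (theta - theta0)``; the intercepts
    absorb any residual drift at the empirical fixed point, so the slope
    block (the Jacobian) is invariant to it.  Returns the matrix, its
    eigenvalues ordered by real part, and standard errors propagated from
    the fit covariance.  A rank-deficient design (e.g. theta constant)
    leaves the corresponding columns unidentifiable and is reported as NaN.
    """
    if window.n_points < 5:
        raise ValueError("window must contain at least 5 points")
    dr = window.r - window.r0
    dth = window.theta - window.theta0
    b1, r2_r, cov1 = _rowfit_r2(dr, dth, window.v_r)
    b2, r2_t, cov2 = _rowfit_r2(dr, dth, window.v_theta)
    A = np.array([b1, b2])
    A_se = np.sqrt(np.abs(np.array([[cov1[0, 0], cov1[1, 1]], [cov2[0, 0], cov2[1, 1]]])))
    lam, se, is_complex = _eigen_with_se(A, cov1, cov2)
    return JacobianEstimate(A, A_se, r2_r, r2_t, lam, se, is_complex, window.n_points)


def estimate_jacobian_cartesian(polar_track: PolarTrack,
                                window: LinearizationWindow) -> JacobianEstimate:
    """Cross-check Jacobian fitted in Cartesian deviations on the same window.

    Fits ``v_x ~ c1 + a11 (x - x0) + a12 (y - y0)`` and
    ``v_y ~ c2 + a21 (x - x0) + a22 (y - y0)`` where ``(x0, y0)`` is the
    t = 0 point, using the attractor-relative Cartesian coordinates
    reconstructed from ``(r, theta)``.  The polar fit is the primary
    estimator; this mode exists to confirm that the inferred stability does
    not hinge on the chart.  Away from the linear regime the two charts
    give different Jacobians (the change of coordinates is nonlinear), so
    agreement is expected in sign and magnitude, not to machine precision.
    """
    if window.n_points < 5:
        raise ValueError("window must contain at least 5 points")
    pt = polar_track
    x = pt.r * np.cos(pt.theta)
    y = pt.r * np.sin(pt.theta)
    sel = slice(window.lo, window.hi + 1)
    dx = x[sel] - x[window.i0]
    dy = y[sel] - y[window.i0]
    b1, r2_x, cov1 = _rowfit_r2(dx, dy, pt.v_x[sel])
    b2, r2_y, cov2 = _rowfit_r2(dx, dy, pt.v_y[sel])
    A = np.array([b1, b2])
    A_se = np.sqrt(np.abs(np.array([[cov1[0, 0], cov1[1, 1]], [cov2[0, 0], cov2[1, 1]]])))
    lam, se, is_complex = _eigen_with_se(A, cov1, cov2)
    return JacobianEstimate(A, A_se, r2_x, r2_y, lam, se, is_complex, window.n_points)


def classify(est: JacobianEstimate) -> str:
    """Stability class from the Lyapunov coefficients' signs.

    Both real parts negative => stable; both positive => unstable; opposite
    => metastable (saddle).  An eigenvalue whose real part is smaller than
    its standard error leaves the sign uncertain => indeterminate.
    """
    re = est.eigenvalues.real
    if not np.all(np.isfinite(re)):
        return "indeterminate"
    if np.any(np.abs(re) < est.eigen_se):
        return "indeterminate"
    if np.all(re < 0):
        return "stable"
    if np.all(re > 0):
        return "unstable"
    return "metastable"


def eigenvalue_timeseries(polar_track: PolarTrack, window: LinearizationWindow,
                          min_points=5) -> pd.DataFrame:
    """Lyapunov coefficients re-estimated along the linearization window.

    At each time point the Jacobian is refitted on the sub-window reaching
    back to the window's outer edge (the end farthest from contact), so the
    series converges onto the full-window estimate; sub-windows below
    ``min_points`` points are dropped.
    """
    if window.n_points < 6:
        raise ValueError("window too short for a time series")
    pt = polar_track
    rows = []
    for i in range(window.lo + min_points - 1, window.hi + 1):
        sub = LinearizationWindow(
            lo=window.lo, hi=i, i0=window.i0, r0=window.r0, theta0=window.theta0,
            r=pt.r[window.lo : i + 1], theta=pt.theta[window.lo : i + 1],
            v_r=pt.v_r[window.lo : i + 1], v_theta=pt.v_theta[window.lo : i + 1],
            r2_vr=np.nan, r2_vtheta=np.nan,
        )
        est = estimate_jacobian(sub)
        rows.append(
            {
                "t": int(pt.t[i]),
                "lambda1": est.eigenvalues[0].real,
                "lambda2": est.eigenvalues[1].real,
                "se1": est.eigen_se[0],
                "se2": est.eigen_se[1],
                "complex": est.complex_flag,
            }
        )
    return pd.DataFrame(rows)


def analyze_encounters(pbmc_tracks, tumor_tracks, config=None):
    """Full per-encounter stability pipeline.

    For every (TC, PBMC) pair whose minimal distance is within the physical
    interaction range (stable candidates) or which exhibits a dr/dtheta
    changepoint (metastable candidates): rebase, estimate the interaction
    range (falling back to the configured default when no changepoint is
    found), select the linearization window, estimate the Jacobian and
    classify.  Returns ``(results, scatter, attractors)`` where ``scatter``
    is the (lambda1, lambda2) table, one row per classified encounter.
    """
    config = config or StabilityConfig()
    if not tumor_tracks:
        raise ValueError("need at least one tumor track")
    attractors = [build_attractor(tc, pbmc_tracks, config) for tc in tumor_tracks]
    results = []
    for att in attractors:
        ranges = []
        for pb in pbmc_tracks:
            if len(pb) < 6:
                continue
            pt = rebase_polar(pb, att, config.dt)
            min_r = float(pt.r[pt.i0])
            if min_r > config.max_candidate_radius:
                continue
            try:
                rng = estimate_interaction_range(pt, bic_margin=config.bic_margin)
            except ValueError:
                rng = RangeEstimate(False, None, (), 1, np.nan, np.nan)
            if min_r > att.physical_interaction_range and not rng.detected:
                continue
            # candidate ranges: the detected changepoint and the configured
            # default; the linearization window is by definition the largest
            # one meeting the R^2 bound, so keep the candidate producing it
            candidates = []
            if rng.detected and rng.range_um and rng.range_um > min_r:
                candidates.append(rng.range_um)
            candidates.append(config.default_interaction_range)
            window, interaction_range = None, candidates[0]
            for cand in candidates:
                w = select_linearization_window(
                    pt, cand, config.r2_min, config.min_window_points
                )
                if w is not None and (window is None or w.n_points > window.n_points):
                    window, interaction_range = w, cand
            if window is None:
                results.append(
                    StabilityResult(pb.track_id, att.tc_id, "indeterminate", None, None,
                                    interaction_range, None, None)
                )
                continue
            est = estimate_jacobian(window)
            label = classify(est)
            series = (
                eigenvalue_timeseries(pt, window) if window.n_points >= 6 else None
            )
            att.basin_members.append(pb.track_id)
            ranges.append(interaction_range)
            results.append(
                StabilityResult(pb.track_id, att.tc_id, label, est, series,
                                interaction_range, window.linearization_range, window)
            )
        if ranges:
            att.interaction_range = float(np.median(ranges))

    scatter = pd.DataFrame(
        [
            {
                "pbmc_id": r.pbmc_id,
                "tc_id": r.tc_id,
                "lambda1": r.jacobian.eigenvalues[0].real,
                "lambda2": r.jacobian.eigenvalues[1].real,
                "se1": r.jacobian.eigen_se[0],
                "se2": r.jacobian.eigen_se[1],
                "class": r.classification,
            }
            for r in results
            if r.jacobian is not None
        ]
    )
    return results, scatter, attractors
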