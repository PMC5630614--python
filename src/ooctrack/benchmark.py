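"""Seeded validation studies with known ground truth.

Every function takes a seed and returns plain summary numbers, so the test
suite and the acceptance script can share one implementation: encounter
classification/eigenvalue recovery over the standard generator grid,
end-to-end tracking on rendered benchmark scenes, step-distribution model
selection, motion-phenotype recovery, and interaction-range changepoint
detection on constructed polar profiles.
"""

from __future__ import annotations

import numpy as np

from . import descriptors, synth, tracking
from .stability import (
    PolarTrack,
    StabilityConfig,
    analyze_encounters,
    estimate_interaction_range,
)

#: ground-truth stability class produced by each standard generator
EXPECTED_CLASS = {"stable": "stable", "saddle": "metastable", "unstable": "unstable"}


def evaluate_encounter_grid(seed=0, n_encounters=100, kinds=("stable", "saddle", "unstable")):
    """Classification accuracy and eigenvalue recovery per generator regime.

    Returns ``{kind: {"accuracy", "rmse_rel", "n", "n_classified"}}`` where
    ``rmse_rel`` holds the RMS eigenvalue error relative to each true
    eigenvalue's magnitude (eigenvalues matched by real-part order).
    """
    cfg = StabilityConfig(dt=0.5)
    out = {}
    for kind in kinds:
        pbmc, tumor, A = synth.simulate_encounter_ensemble(kind, n_encounters, seed=seed)
        results, scatter, _ = analyze_encounters(pbmc, [tumor], cfg)
        lam_true = np.sort(np.diag(A))
        acc = float(np.mean([r.classification == EXPECTED_CLASS[kind] for r in results]))
        est = np.sort(scatter[["lambda1", "lambda2"]].to_numpy(), axis=1)
        rmse = np.sqrt(((est - lam_true) ** 2).mean(axis=0)) / np.abs(lam_true)
        out[kind] = {
            "accuracy": acc,
            "rmse_rel": tuple(float(v) for v in rmse),
            "n": len(results),
            "n_classified": len(scatter),
        }
    return out


def evaluate_tracking_benchmark(seed=0, n_frames=100):
    """Render the tracking benchmark scene, track it, and score the result.

    Links are scored against the ground-truth table: each recovered track
    point is matched to the nearest truth cell in its frame; a link counts
    as recovered when two consecutive-frame points match the same truth
    cell, and every change of matched identity within one track is an
    identity switch.
    """
    tracks, params = synth.simulate_tracking_benchmark(seed=seed, n_frames=n_frames)
    stack, truth = synth.render_stack(tracks, params, seed=seed)
    recovered = tracking.track_stack(stack, tracking.TrackingConfig(), px_per_um=1.0)

    by_frame = {
        f: (g["x_px"].to_numpy(), g["y_px"].to_numpy(), g["cell_id"].to_numpy())
        for f, g in truth.groupby("frame")
    }
    total_links = sum(len(g) - 1 for _, g in truth.groupby("cell_id"))
    n_links, n_switches = 0, 0
    for tr in recovered:
        ids = np.empty(len(tr), dtype=int)
        for k, (f, x, y) in enumerate(zip(tr.frames, tr.x, tr.y)):
            tx, ty, tid = by_frame[int(f)]
            ids[k] = tid[np.argmin(np.hypot(tx - x, ty - y))]
        n_switches += int((ids[1:] != ids[:-1]).sum())
        n_links += int(((ids[1:] == ids[:-1]) & (np.diff(tr.frames) == 1)).sum())
    return {
        "n_tracks": len(recovered),
        "n_immune": sum(t.population == "immune" for t in recovered),
        "n_tumor": sum(t.population == "tumor" for t in recovered),
        "link_recovery": n_links / total_links,
        "identity_switches": n_switches,
        "min_duration": min(t.duration for t in recovered),
        "total_links": total_links,
    }


def exact_linear_polar_track(A, n=40, r0=20.0, theta0=0.5, dt=0.5, offset=(10.0, 0.6)):
    """PolarTrack sampled from the exact linear flow with exact velocities.

    Positions follow ``exp(A t)`` applied to the initial offset and the
    velocity arrays are evaluated analytically as ``A @ delta``, so a linear
    regression must recover ``A`` to machine precision — the noise-free
    exactness reference for the Jacobian estimator.
    """
    from scipy.linalg import expm

    A = np.asarray(A, dtype=float)
    ts = np.arange(n) * dt
    delta = np.array([expm(A * t) @ np.asarray(offset, float) for t in ts])
    vel = delta @ A.T
    r = r0 + delta[:, 0]
    theta = theta0 + delta[:, 1]
    t_idx = int(np.argmin(r)) - np.arange(n)
    z = np.zeros(n)
    return PolarTrack(0, r, theta, vel[:, 0], vel[:, 1], z, z, t_idx, np.arange(n), dt)


def _polar_track_from_profile(r, theta, dt=2.0):
    """Wrap a constructed r(theta) profile as a PolarTrack (velocities unused)."""
    r = np.asarray(r, dtype=float)
    theta = np.asarray(theta, dtype=float)
    n = len(r)
    z = np.zeros(n)
    t = int(np.argmin(r)) - np.arange(n)
    return PolarTrack(0, r, theta, z, z, z, z, t, np.arange(n), dt)


def make_breakpoint_polar_track(seed, r_break=50.0, slope_outer=62.67, slope_inner=15.0,
                                noise_sd=1.5, n=80):
    """Polar profile with an abrupt dr/dtheta change at ``r_break``.

    The cell approaches steeply (slope ``slope_outer`` um/rad) down to the
    breakpoint, then shallowly (``slope_inner``); Gaussian noise of standard
    deviation ``noise_sd`` um is added to r.
    """
    rng = np.random.default_rng(seed)
    th_break = 1.0
    th1 = np.linspace(th_break + 40.0 / slope_outer, th_break, n // 2, endpoint=False)
    th2 = np.linspace(th_break, th_break - 35.0 / slope_inner, n - n // 2)
    th = np.concatenate([th1, th2])
    r = np.where(
        th >= th_break,
        r_break + slope_outer * (th - th_break),
        r_break + slope_inner * (th - th_break),
    )
    return _polar_track_from_profile(r + rng.normal(0.0, noise_sd, n), th)


def make_linear_polar_track(seed, slope=40.0, noise_sd=1.5, n=80):
    """Single-slope polar profile: no changepoint present."""
    rng = np.random.default_rng(seed)
    th = np.linspace(2.2, 0.2, n)
    r = 10.0 + slope * (th - 0.2)
    return _polar_track_from_profile(r + rng.normal(0.0, noise_sd, n), th)


def evaluate_changepoint(seed=0, n_replicates=50, r_break=50.0):
    """Breakpoint detection study: replicated with/without a changepoint.

    Returns the detection rate and worst relative range error on tracks with
    a breakpoint at ``r_break``, and the false-positive rate on single-slope
    tracks of matching noise.
    """
    rng = np.random.default_rng(seed)
    errors, detected = [], 0
    for _ in range(n_replicates):
        est = estimate_interaction_range(make_breakpoint_polar_track(int(rng.integers(2**31))))
        if est.detected:
            detected += 1
            errors.append(abs(est.range_um - r_break) / r_break)
    false_pos = sum(
        estimate_interaction_range(make_linear_polar_track(int(rng.integers(2**31)))).detected
        for _ in range(n_replicates)
    )
    return {
        "detection_rate": detected / n_replicates,
        "max_rel_error": max(errors) if errors else np.inf,
        "mean_rel_error": float(np.mean(errors)) if errors else np.inf,
        "false_positive_rate": false_pos / n_replicates,
        "n": n_replicates,
    }


def evaluate_branch_selection(seed=0, n_samples=5000, n_replicates=100):
    """Fraction of step-length branches assigned their generating model.

    Each replicate draws one exponential and one half-Gaussian sample of
    ``n_samples`` magnitudes and fits both; a correct call names the
    generating family.
    """
    rng = np.random.default_rng(seed)
    correct = 0
    for _ in range(n_replicates):
        expo = rng.exponential(2.0, n_samples)
        gaus = np.abs(rng.normal(0.0, 2.0, n_samples))
        correct += descriptors.fit_branch(expo).model == "exponential"
        correct += descriptors.fit_branch(gaus).model == "gaussian"
    return {"rate": correct / (2 * n_replicates), "n": 2 * n_replicates}


def evaluate_motion_classifier(seed=0, n_replicates=50, n_cells=25, n_steps=150):
    """Fraction of simulated ensembles assigned their generating phenotype."""
    rng = np.random.default_rng(seed)
    labels = synth.PHENOTYPE_LABELS
    correct = 0
    for i in range(n_replicates):
        label = labels[i % len(labels)]
        params = synth.PhenotypeParams(label=label)
        walks = synth.simulate_phenotype_walks(
            params, n_cells, n_steps, seed=int(rng.integers(2**31))
        )
        steps = descriptors.pool_steps(walks)
        motion = descriptors.classify_motion(descriptors.fit_all_branches(steps))
        correct += motion.label == label
    return {"rate": correct / n_replicates, "n": n_replicates}
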