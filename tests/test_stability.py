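import numpy as np
import pytest

from conftest import exact_linear_polar_track
from ooctrack import benchmark, synth
from ooctrack import stability as stab
from ooctrack.types import Track


# ------------------------------------------------------------ attractor/polar
def test_physical_interaction_range_is_diameter_sum():
    att = stab.TumorAttractor(0, 0.0, 0.0, tc_diameter=20.0, pbmc_mean_diameter=9.0)
    assert att.physical_interaction_range == 29.0


def test_build_attractor_time_mean_and_warning():
    wander = Track(5, "tumor", np.arange(4), np.array([0.0, 0.0, 30.0, 30.0]),
                   np.zeros(4))
    with pytest.warns(UserWarning, match="fixed-point"):
        att = stab.build_attractor(wander, config=stab.StabilityConfig())
    assert att.x0 == pytest.approx(15.0)
    assert att.tc_id == 5


def test_rebase_polar_geometry():
    tc = Track(1, "tumor", np.arange(5), np.full(5, 10.0), np.full(5, 10.0))
    att = stab.build_attractor(tc, config=stab.StabilityConfig())
    # quarter circle of radius 20 around the TC, then closer approach
    ang = np.array([0.0, 0.25, 0.5, 0.75, 1.0]) * np.pi / 2
    r = np.array([20.0, 20.0, 20.0, 20.0, 5.0])
    pb = Track(0, "immune", np.arange(5), 10.0 + r * np.cos(ang), 10.0 + r * np.sin(ang))
    pt = stab.rebase_polar(pb, att, dt=2.0)
    assert np.allclose(pt.r, r)
    assert np.allclose(pt.theta, ang)  # unwrapped, monotone here
    assert pt.i0 == 4  # t = 0 at the closest approach
    assert pt.t[pt.i0] == 0 and pt.t[0] == 4


# ------------------------------------------------- noiseless linear exactness
@pytest.mark.parametrize("A", [np.diag([-0.5, -0.2]),
                               np.array([[-0.3, 0.1], [0.05, 0.3]]),
                               np.diag([0.2, 0.5])])
def test_noiseless_jacobian_exact(A):
    pt = exact_linear_polar_track(A)
    win = stab.select_linearization_window(pt, interaction_range=1e9)
    assert win is not None and win.n_points == len(pt.r)
    est = stab.estimate_jacobian(win)
    assert np.abs(est.A - A).max() < 1e-8
    assert np.abs(np.sort(est.eigenvalues.real) - np.sort(np.linalg.eigvals(A).real)).max() < 1e-8


def test_noiseless_eigen_series_constant():
    A = np.diag([-0.5, -0.2])
    pt = exact_linear_polar_track(A)
    win = stab.select_linearization_window(pt, interaction_range=1e9)
    series = stab.eigenvalue_timeseries(pt, win)
    assert series["lambda1"].std() < 1e-8
    assert series["lambda2"].std() < 1e-8
    assert series["lambda1"].iloc[-1] == pytest.approx(-0.5, abs=1e-8)


# -------------------------------------------------------- structural invariants
def test_trace_determinant_identities():
    rng = np.random.default_rng(0)
    for _ in range(20):
        A = rng.normal(0, 0.4, (2, 2))
        pt = exact_linear_polar_track(A, offset=(8.0, 0.5))
        win = stab.select_linearization_window(pt, interaction_range=1e9)
        est = stab.estimate_jacobian(win)
        lam = est.eigenvalues
        assert abs(lam.sum() - np.trace(est.A)) < 1e-10
        assert abs(np.prod(lam) - np.linalg.det(est.A)) < 1e-10


def test_time_reversal_flips_eigenvalue_signs():
    A = np.array([[-0.4, 0.1], [0.0, -0.15]])
    pt = exact_linear_polar_track(A)
    win = stab.select_linearization_window(pt, interaction_range=1e9)
    fwd = stab.estimate_jacobian(win)
    rev = stab.LinearizationWindow(
        lo=win.lo, hi=win.hi, i0=win.i0, r0=win.r0, theta0=win.theta0,
        r=win.r[::-1].copy(), theta=win.theta[::-1].copy(),
        v_r=-win.v_r[::-1].copy(), v_theta=-win.v_theta[::-1].copy(),
        r2_vr=np.nan, r2_vtheta=np.nan,
    )
    bwd = stab.estimate_jacobian(rev)
    assert np.allclose(np.sort(bwd.eigenvalues.real),
                       -np.sort(fwd.eigenvalues.real)[::-1], atol=1e-10)


def test_window_monotone_in_r2_threshold():
    tr, A = synth.simulate_polar_linear_encounter(
        np.diag([-0.5, -0.2]), noise_frac=0.15, seed=3, n_steps=120, dt=0.5
    )
    tc = Track(9, "tumor", np.arange(len(tr)), np.full(len(tr), 100.0), np.full(len(tr), 100.0))
    att = stab.build_attractor(tc, config=stab.StabilityConfig(dt=0.5))
    pt = stab.rebase_polar(tr, att, dt=0.5)
    sizes = []
    for r2_min in (0.5, 0.8, 0.9, 0.95, 0.99):
        win = stab.select_linearization_window(pt, interaction_range=50.0, r2_min=r2_min)
        sizes.append(win.n_points if win is not None else 0)
    assert sizes == sorted(sizes, reverse=True)


def test_seed_determinism_of_analysis():
    grid_a = benchmark.evaluate_encounter_grid(seed=5, n_encounters=5, kinds=("stable",))
    grid_b = benchmark.evaluate_encounter_grid(seed=5, n_encounters=5, kinds=("stable",))
    assert grid_a == grid_b


# ------------------------------------------------------------ window edge cases
def test_window_none_outside_interaction_range():
    pt = exact_linear_polar_track(np.diag([-0.5, -0.2]), offset=(30.0, 0.5))
    # trajectory never comes inside an (unrealistically small) range
    assert stab.select_linearization_window(pt, interaction_range=1.0) is None


def test_window_none_when_too_few_points():
    pt = exact_linear_polar_track(np.diag([-0.5, -0.2]), n=4)
    assert stab.select_linearization_window(pt, interaction_range=1e9, min_points=5) is None


def test_estimate_jacobian_needs_points():
    pt = exact_linear_polar_track(np.diag([-0.5, -0.2]), n=12)
    win = stab.select_linearization_window(pt, interaction_range=1e9)
    short = stab.LinearizationWindow(
        lo=0, hi=3, i0=0, r0=win.r0, theta0=win.theta0, r=win.r[:4], theta=win.theta[:4],
        v_r=win.v_r[:4], v_theta=win.v_theta[:4], r2_vr=1.0, r2_vtheta=1.0,
    )
    with pytest.raises(ValueError):
        stab.estimate_jacobian(short)


# ----------------------------------------------------------------- changepoint
def test_changepoint_detected_within_tolerance():
    for seed in range(10):
        est = stab.estimate_interaction_range(benchmark.make_breakpoint_polar_track(seed))
        assert est.detected
        assert abs(est.range_um - 50.0) / 50.0 < 0.15


def test_no_changepoint_on_single_slope():
    for seed in range(10):
        est = stab.estimate_interaction_range(benchmark.make_linear_polar_track(seed))
        assert not est.detected
        assert est.range_um is None


def test_three_segment_supersedes_when_track_leaves():
    rng = np.random.default_rng(3)
    thA = np.linspace(2.0, 1.0, 30)
    rA = 120 - 70 * (2.0 - thA) + rng.normal(0, 2, 30)
    thB = np.linspace(1.0, 0.2, 25)
    rB = 50 - 31.17 * (1.0 - thB) + rng.normal(0, 1, 25)
    thC = np.linspace(0.2, -0.8, 25)
    rC = rB[-1] + 37.3 * (0.2 - thC) + rng.normal(0, 1, 25)
    pt = benchmark._polar_track_from_profile(
        np.concatenate([rA, rB, rC]), np.concatenate([thA, thB, thC])
    )
    est = stab.estimate_interaction_range(pt)
    assert est.detected and est.n_segments == 3
    assert est.range_um == pytest.approx(50.0, rel=0.15)


def test_changepoint_needs_enough_points():
    pt = benchmark._polar_track_from_profile(np.linspace(60, 10, 6), np.linspace(2, 0, 6))
    with pytest.raises(ValueError):
        stab.estimate_interaction_range(pt)


# -------------------------------------------------------------- classification
def _estimate(lams, ses):
    lam = np.asarray(lams, dtype=complex)
    return stab.JacobianEstimate(np.eye(2), np.eye(2), 1.0, 1.0, lam,
                                 np.asarray(ses, float), False, 20)


@pytest.mark.parametrize("lams,ses,label", [
    ((-0.5, -0.2), (0.05, 0.05), "stable"),
    ((0.2, 0.5), (0.05, 0.05), "unstable"),
    ((-0.3, 0.3), (0.05, 0.05), "metastable"),
    ((-0.3, 0.3), (0.05, 0.4), "indeterminate"),  # |Re| < SE
    ((np.nan, 0.3), (0.05, 0.05), "indeterminate"),
])
def test_classify_sign_patterns(lams, ses, label):
    assert stab.classify(_estimate(lams, ses)) == label


def test_complex_eigenvalues_flagged():
    A = np.array([[0.0, -1.0], [1.0, 0.0]])  # pure rotation
    pt = exact_linear_polar_track(A, offset=(5.0, 0.3), n=20, dt=0.1)
    win = stab.select_linearization_window(pt, interaction_range=1e9)
    est = stab.estimate_jacobian(win)
    assert est.complex_flag
    assert np.allclose(est.eigenvalues.imag, [-1.0, 1.0], atol=1e-8)


# ------------------------------------------------------------ full pipeline
def test_analyze_encounters_outputs():
    pbmc, tumor, A = synth.simulate_encounter_ensemble("stable", 8, seed=2)
    results, scatter, attractors = stab.analyze_encounters(
        pbmc, [tumor], stab.StabilityConfig(dt=0.5)
    )
    assert len(results) == 8
    assert set(scatter.columns) >= {"pbmc_id", "tc_id", "lambda1", "lambda2",
                                    "se1", "se2", "class"}
    assert len(attractors) == 1
    assert attractors[0].basin_members  # stable encounters populate the basin
    for r in results:
        if r.classification == "stable":
            assert r.window is not None
            assert r.jacobian.eigenvalues[0].real < 0


def test_analyze_encounters_requires_tumor():
    with pytest.raises(ValueError):
        stab.analyze_encounters([], [], stab.StabilityConfig())


# --------------------------------------------------- Cartesian cross-check
def test_cartesian_mode_recovers_cartesian_linear_system():
    from scipy.linalg import expm

    A = np.array([[-0.5, 0.1], [0.05, -0.2]])
    dt, n = 0.1, 60
    d0 = np.array([15.0, 8.0])
    pos = np.array([expm(A * k * dt) @ d0 for k in range(n)])
    tc = Track(9, "tumor", np.arange(n), np.full(n, 100.0), np.full(n, 100.0))
    att = stab.build_attractor(tc, config=stab.StabilityConfig())
    pb = Track(0, "immune", np.arange(n), 100.0 + pos[:, 0], 100.0 + pos[:, 1])
    pt = stab.rebase_polar(pb, att, dt=dt)
    win = stab.LinearizationWindow(
        0, n - 1, pt.i0, float(pt.r[pt.i0]), float(pt.theta[pt.i0]),
        pt.r.copy(), pt.theta.copy(), pt.v_r.copy(), pt.v_theta.copy(), 1.0, 1.0,
    )
    est = stab.estimate_jacobian_cartesian(pt, win)
    true = np.sort(np.linalg.eigvals(A).real)
    assert np.abs(np.sort(est.eigenvalues.real) - true).max() < 0.02
    assert est.r2_vr > 0.999 and est.r2_vtheta > 0.999


def test_cartesian_mode_sign_consistent_on_stable_encounters():
    # the chart change is nonlinear, so only the stability signs are expected
    # to agree with the primary polar fit, not the eigenvalue magnitudes
    cfg = stab.StabilityConfig(dt=0.5)
    pbmc, tumor, _ = synth.simulate_encounter_ensemble("stable", 6, seed=3)
    results, _, atts = stab.analyze_encounters(pbmc, [tumor], cfg)
    checked = 0
    for res in results:
        if res.window is None or res.classification != "stable":
            continue
        tr = next(t for t in pbmc if t.track_id == res.pbmc_id)
        pt = stab.rebase_polar(tr, atts[0], cfg.dt)
        est = stab.estimate_jacobian_cartesian(pt, res.window)
        assert est.eigenvalues.real.max() <= 0.0
        assert stab.classify(est) in ("stable", "indeterminate")
        checked += 1
    assert checked >= 4


def test_cartesian_mode_needs_points():
    pt = exact_linear_polar_track(np.diag([-0.5, -0.2]))
    win = stab.select_linearization_window(pt, interaction_range=1e9)
    small = stab.LinearizationWindow(
        0, 2, pt.i0, win.r0, win.theta0, pt.r[:3], pt.theta[:3],
        pt.v_r[:3], pt.v_theta[:3], 1.0, 1.0,
    )
    with pytest.raises(ValueError):
        stab.estimate_jacobian_cartesian(pt, small)
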