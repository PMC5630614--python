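import numpy as np
import pytest

from ooctrack import synth, tracking
from ooctrack.types import Detection, Track


def _disk_image(centers_radii, shape=(96, 96), intensity=200.0):
    """Noise-free image of bright disks; centers in bottom-left pixel coords."""
    img = np.zeros(shape, dtype=float)
    h = shape[0]
    for (x, y, r) in centers_radii:
        row = (h - 1) - y
        rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
        cover = np.clip(r + 0.5 - np.hypot(rr - row, cc - x), 0, 1)
        img = np.maximum(img, intensity * cover)
    return img.astype(np.uint8)


# ---------------------------------------------------------------- detection
def test_detect_cells_exact_centers_and_radii():
    img = _disk_image([(30, 40, 5), (70, 20, 10)])
    dets = tracking.detect_cells(img, (3, 12))
    assert len(dets) == 2
    by_r = sorted(dets, key=lambda d: d.radius_px)
    assert (by_r[0].x_px, by_r[0].y_px, by_r[0].radius_px) == (30, 40, 5)
    assert (by_r[1].x_px, by_r[1].y_px, by_r[1].radius_px) == (70, 20, 10)


def test_detect_cells_blank_image():
    img = np.zeros((64, 64), dtype=np.uint8)
    assert tracking.detect_cells(img, (3, 10)) == []


def test_detect_cells_suppresses_centers_inside_larger_cells():
    """No surviving detection center may lie inside another detection."""
    img = _disk_image([(48, 48, 10)])
    dets = tracking.detect_cells(img, (3, 12))
    assert len(dets) >= 1
    for i, a in enumerate(dets):
        for b in dets[i + 1:]:
            assert np.hypot(a.x_px - b.x_px, a.y_px - b.y_px) >= max(a.radius_px, b.radius_px)


def test_detect_cells_rejects_color_input():
    with pytest.raises(ValueError):
        tracking.detect_cells(np.zeros((4, 4, 3)), (3, 5))


def test_discriminate_boundary_belongs_to_tumor():
    r_thr = 6.0
    thr = np.pi * r_thr**2
    dets = [Detection(0, 0, 0, 5.9), Detection(0, 0, 0, 6.0), Detection(0, 0, 0, 6.1)]
    pops = [d.population for d in tracking.discriminate(dets, thr)]
    assert pops == ["immune", "tumor", "tumor"]


# ------------------------------------------------------------------ linking
def _frames_from_positions(per_frame, population="immune"):
    return {
        f: [Detection(f, x, y, 4.0, population) for (x, y) in pts]
        for f, pts in per_frame.items()
    }


def test_link_two_parallel_tracks():
    per_frame = {f: [(10.0 + f, 10.0), (40.0, 10.0 + f)] for f in range(6)}
    tracks = tracking.link_tracks(_frames_from_positions(per_frame), tracking.TrackingConfig())
    assert len(tracks) == 2
    assert all(len(t) == 6 for t in tracks)


def test_link_respects_dmax():
    """A jump beyond dmax breaks the track instead of linking."""
    per_frame = {0: [(10.0, 10.0)], 1: [(10.0, 10.0)], 2: [(40.0, 10.0)]}
    cfg = tracking.TrackingConfig(dmax_immune=10.0, gap_immune=1)
    tracks = tracking.link_tracks(_frames_from_positions(per_frame), cfg)
    assert sorted(len(t) for t in tracks) == [1, 2]


def test_conflictual_stop_rule():
    """Two tracks sharing one nearest detection both stop; it seeds a new track."""
    per_frame = {
        0: [(10.0, 10.0), (18.0, 10.0)],
        1: [(14.0, 10.0)],
        2: [(14.0, 10.0)],
    }
    cfg = tracking.TrackingConfig(dmax_immune=10.0, gap_immune=1)
    tracks = tracking.link_tracks(_frames_from_positions(per_frame), cfg)
    lengths = sorted((t.frames[0], len(t)) for t in tracks)
    # both frame-0 tracks stopped at length 1; the shared detection starts at frame 1
    assert lengths == [(0, 1), (0, 1), (1, 2)]


def test_gap_closure_within_budget():
    per_frame = {0: [(10.0, 10.0)], 1: [], 2: [(11.0, 10.0)]}
    cfg = tracking.TrackingConfig(gap_immune=2)
    tracks = tracking.link_tracks(_frames_from_positions(per_frame), cfg)
    assert len(tracks) == 1
    assert list(tracks[0].frames) == [0, 2]


def test_gap_budget_exhausted_starts_new_track():
    per_frame = {0: [(10.0, 10.0)], 1: [], 2: [], 3: [(11.0, 10.0)]}
    cfg = tracking.TrackingConfig(gap_immune=2)
    tracks = tracking.link_tracks(_frames_from_positions(per_frame), cfg)
    assert len(tracks) == 2


def test_linking_independent_of_detection_order():
    rng = np.random.default_rng(0)
    per_frame = {f: [(10.0 + f, 10.0), (30.0, 10.0 + f), (50.0 + f, 50.0)] for f in range(8)}
    base = _frames_from_positions(per_frame)
    shuffled = {f: list(rng.permutation(len(d))) for f, d in base.items()}
    perm = {f: [base[f][i] for i in shuffled[f]] for f in base}
    t1 = tracking.link_tracks(base, tracking.TrackingConfig())
    t2 = tracking.link_tracks(perm, tracking.TrackingConfig())
    key = lambda ts: sorted((tuple(t.frames), tuple(t.x), tuple(t.y)) for t in ts)
    assert key(t1) == key(t2)


def test_populations_linked_independently():
    per_frame = {
        f: [Detection(f, 10.0, 10.0, 4.0, "immune"), Detection(f, 12.0, 10.0, 11.0, "tumor")]
        for f in range(5)
    }
    tracks = tracking.link_tracks(per_frame, tracking.TrackingConfig())
    assert sorted(t.population for t in tracks) == ["immune", "tumor"]
    assert all(len(t) == 5 for t in tracks)


# ------------------------------------------------------------------- filter
def test_min_duration_filter_boundary():
    mk = lambda n: Track(n, "immune", np.arange(n), np.zeros(n), np.zeros(n))
    kept = tracking.filter_tracks([mk(19), mk(20), mk(21)], min_duration=20)
    assert sorted(len(t) for t in kept) == [20, 21]


# -------------------------------------------------------------------- merge
def test_merge_tumor_cylindrical_long_gap():
    """Tumor fragments merge across long gaps when spatially close."""
    a = Track(0, "tumor", np.arange(0, 10), np.full(10, 50.0), np.full(10, 50.0))
    b = Track(1, "tumor", np.arange(45, 55), np.full(10, 52.0), np.full(10, 50.0))
    cfg = tracking.TrackingConfig()
    merged = tracking.merge_tracks([a, b], cfg)
    assert len(merged) == 1
    assert merged[0].provenance == [0, 1]


def test_merge_tumor_rejects_beyond_radius():
    a = Track(0, "tumor", np.arange(0, 10), np.full(10, 50.0), np.full(10, 50.0))
    b = Track(1, "tumor", np.arange(45, 55), np.full(10, 58.0), np.full(10, 50.0))
    assert len(tracking.merge_tracks([a, b], tracking.TrackingConfig())) == 2


def test_merge_immune_spherical_counts_time():
    """The immune merge distance is spherical in (x, y, c*t)."""
    cfg = tracking.TrackingConfig(merge_radius_immune=5.0, merge_time_scale=1.0)
    a = Track(0, "immune", np.arange(0, 5), np.full(5, 10.0), np.full(5, 10.0))
    # spatial gap 3, time gap 3 -> sqrt(9 + 9) = 4.24 <= 5: merge
    b = Track(1, "immune", np.arange(7, 12), np.full(5, 13.0), np.full(5, 10.0))
    assert len(tracking.merge_tracks([a, b], cfg)) == 1
    # spatial gap 4, time gap 4 -> sqrt(32) = 5.66 > 5: keep apart
    c = Track(2, "immune", np.arange(0, 5), np.full(5, 30.0), np.full(5, 10.0))
    d = Track(3, "immune", np.arange(8, 12), np.full(4, 34.0), np.full(4, 10.0))
    assert len(tracking.merge_tracks([c, d], cfg)) == 2


def test_merge_rejects_mixed_populations():
    a = Track(0, "tumor", np.arange(3), np.zeros(3), np.zeros(3))
    b = Track(1, "immune", np.arange(3), np.zeros(3), np.zeros(3))
    with pytest.raises(ValueError):
        tracking.merge_tracks([a, b], tracking.TrackingConfig())


def test_merge_closest_pair_first():
    """With two candidates for one fragment, the spatially closer wins."""
    cfg = tracking.TrackingConfig()
    a = Track(0, "tumor", np.arange(0, 5), np.full(5, 50.0), np.full(5, 50.0))
    b = Track(1, "tumor", np.arange(10, 15), np.full(5, 51.0), np.full(5, 50.0))
    c = Track(2, "tumor", np.arange(10, 15), np.full(5, 54.0), np.full(5, 50.0))
    merged = tracking.merge_tracks([a, b, c], cfg)
    prov = sorted(tuple(t.provenance) or (t.track_id,) for t in merged)
    assert ((0, 1) in prov) and not any(0 in p and 2 in p for p in prov)


# -------------------------------------------------------------- config/pipeline
def test_tracking_config_validation():
    with pytest.raises(ValueError):
        tracking.TrackingConfig(dmax_immune=0.0)
    with pytest.raises(ValueError):
        tracking.TrackingConfig(min_duration=1)


def test_track_stack_end_to_end(benchmark_scene):
    _, _, stack, truth = benchmark_scene
    out = tracking.track_stack(stack, tracking.TrackingConfig(), px_per_um=1.0)
    assert sum(t.population == "immune" for t in out) == 20
    assert sum(t.population == "tumor" for t in out) == 3
    assert min(t.duration for t in out) >= 20
    cfg = tracking.TrackingConfig()
    for t in out:
        # no consecutive-frame link exceeds the population's dmax
        dmax = cfg.dmax_immune if t.population == "immune" else cfg.dmax_tumor
        step = np.hypot(np.diff(t.x), np.diff(t.y))
        consecutive = np.diff(t.frames) == 1
        assert np.all(step[consecutive] <= dmax + 1e-9)


# ----------------------------------------------------------------- ROI masks
def test_filter_roi_polygon_masking():
    dets = [Detection(0, 10.0, 10.0, 4.0), Detection(0, 50.0, 50.0, 4.0)]
    square = [(0.0, 0.0), (20.0, 0.0), (20.0, 20.0), (0.0, 20.0)]
    kept = tracking.filter_roi(dets, [square], px_per_um=1.0)
    assert [d.x_px for d in kept] == [10.0]
    assert tracking.filter_roi(dets, [], px_per_um=1.0) == dets
    assert tracking.filter_roi([], [square], px_per_um=1.0) == []


def test_filter_roi_scales_pixels_to_micrometres():
    # detection at 40 px = 20 um when px_per_um = 2
    dets = [Detection(0, 40.0, 40.0, 4.0)]
    square = [(15.0, 15.0), (25.0, 15.0), (25.0, 25.0), (15.0, 25.0)]
    assert tracking.filter_roi(dets, [square], px_per_um=2.0) == dets
    assert tracking.filter_roi(dets, [square], px_per_um=1.0) == []


def test_track_stack_roi_and_detections(benchmark_scene):
    _, _, stack, _ = benchmark_scene
    # mask excludes the tumor column (x ~ 295 um)
    roi = [[(0.0, 0.0), (260.0, 0.0), (260.0, 220.0), (0.0, 220.0)]]
    out, dets = tracking.track_stack(
        stack[:30], tracking.TrackingConfig(), px_per_um=1.0,
        roi_polygons=roi, return_detections=True,
    )
    assert out and all(t.population == "immune" for t in out)
    for frame_dets in dets.values():
        assert all(d.x_px <= 260.0 for d in frame_dets)
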