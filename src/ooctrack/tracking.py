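"""Cell localization and constrained proximity tracking (CPT).

The pipeline block: circular-Hough cell detection per frame, population
discrimination by object area, greedy nearest-neighbour linking with
population-specific maximum displacement and gap limits, a minimum-duration
filter, and iterative track merging (cylindrical in (x, y, t) for the
near-stationary tumor cells, spherical spatio-temporal for the motile immune
cells).

Linking semantics: a track links to the closest unclaimed detection within
``dmax`` of its last position.  When no detection lies within reach the
track enters a gap (missing tracking) and may resume within ``gap`` frames
at the same ``dmax``; when the nearest detection of two active tracks
coincides, both tracks stop (conflictual tracking) and the detection may
seed a new track.  Candidate links are processed in ascending distance with
ties broken by lower track id, which makes the result independent of the
order detections are listed in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import count

import numpy as np
from skimage.feature import canny
from skimage.transform import hough_circle

from .types import Detection, Track


@dataclass
class TrackingConfig:
    """Population-specific constraints of the proximity tracker.

    Defaults: max link displacement 10 px (immune) / 5 px (tumor), track
    gaps of 10 / 50 frames, minimum track duration 20 frames.
    """

    dmax_immune: float = 10.0
    dmax_tumor: float = 5.0
    gap_immune: int = 10
    gap_tumor: int = 50
    min_duration: int = 20
    merge_radius_immune: float = 5.0
    merge_radius_tumor: float = 5.0
    merge_time_scale: float = 1.0  # px per frame, spherical merge only
    hough_radii_immune: tuple = (3, 7)
    hough_radii_tumor: tuple = (8, 14)
    area_threshold_px: float = 120.0
    sensitivity: float = 0.4

    def __post_init__(self):
        if min(self.dmax_immune, self.dmax_tumor) <= 0:
            raise ValueError("dmax must be positive")
        if min(self.gap_immune, self.gap_tumor) <= 0:
            raise ValueError("gap limits must be positive")
        if self.min_duration < 2:
            raise ValueError("min_duration must be >= 2")

    def dmax(self, population):
        return self.dmax_immune if population == "immune" else self.dmax_tumor

    def gap(self, population):
        return self.gap_immune if population == "immune" else self.gap_tumor


def detect_cells(frame_image, radius_range, sensitivity=0.4, frame=0):
    """Detect roughly circular cells in one frame by circular Hough transform.

    Edges from a Canny filter feed a multi-radius Hough accumulator; peaks
    with normalized score above ``sensitivity`` survive a non-maximum
    suppression that forbids any detection whose center lies inside a
    higher-scoring one.  Returns detections in pixel coordinates with a bottom-left
    origin (image rows are flipped).
    """
    img = np.asarray(frame_image)
    if img.ndim != 2:
        raise ValueError("frame_image must be single-channel")
    rmin, rmax = radius_range
    radii = np.arange(int(rmin), int(rmax) + 1)
    edges = canny(img.astype(float) / 255.0, sigma=1.2)
    if not edges.any():
        return []
    accum = hough_circle(edges, radii)

    # candidate peaks per radius; the accumulator is perimeter-normalized
    # (a complete circle of that radius scores ~1)
    cands = []
    thr = max(sensitivity, 1e-6)
    for i, r in enumerate(radii):
        a = accum[i]
        rows, cols = np.nonzero(a >= thr)
        for rr, cc in zip(rows, cols):
            cands.append((float(a[rr, cc]), float(cc), float(rr), float(r)))
    cands.sort(key=lambda t: (-t[0], t[1], t[2], t[3]))

    kept = []
    for score, cx, cy_row, r in cands:
        ok = True
        for _, kx, ky_row, kr in kept:
            dist = np.hypot(cx - kx, cy_row - ky_row)
            # duplicates of one object, and circles whose center falls
            # inside an accepted cell (a cell cannot contain the center
            # of another), are suppressed
            if dist < max(r, kr):
                ok = False
                break
        if ok:
            kept.append((score, cx, cy_row, r))

    h = img.shape[0]
    return [
        Detection(frame=frame, x_px=cx, y_px=(h - 1) - cy_row, radius_px=r)
        for _, cx, cy_row, r in kept
    ]


def discriminate(detections, area_threshold_px):
    """Assign populations by object area: small -> immune, large -> tumor.

    The boundary belongs to the tumor class (area >= threshold => tumor).
    """
    out = []
    for d in detections:
        pop = "tumor" if d.area_px >= area_threshold_px else "immune"
        out.append(Detection(d.frame, d.x_px, d.y_px, d.radius_px, pop))
    return out


class _ActiveTrack:
    __slots__ = ("track_id", "frames", "xs", "ys", "last_frame", "alive")

    def __init__(self, track_id, frame, x, y):
        self.track_id = track_id
        self.frames = [frame]
        self.xs = [x]
        self.ys = [y]
        self.last_frame = frame
        self.alive = True

    def append(self, frame, x, y):
        self.frames.append(frame)
        self.xs.append(x)
        self.ys.append(y)
        self.last_frame = frame


def link_tracks(detections_by_frame, config):
    """Link per-frame detections into tracks, independently per population.

    ``detections_by_frame`` maps frame index -> list of Detection (with
    populations set).  Frames must be processed in increasing order.
    """
    frames = sorted(detections_by_frame)
    if list(frames) != sorted(set(frames)):
        raise ValueError("duplicate frames in input")
    tracks = []
    for pop in ("immune", "tumor"):
        per_frame = {
            f: [d for d in detections_by_frame[f] if d.population == pop]
            for f in frames
        }
        tracks.extend(_link_one_population(per_frame, frames, pop, config))
    return tracks


def _link_one_population(per_frame, frames, population, config):
    dmax = config.dmax(population)
    gap = config.gap(population)
    ids = count(0)
    active: list[_ActiveTrack] = []
    finished: list[_ActiveTrack] = []

    for f in frames:
        dets = per_frame[f]
        positions = [(d.x_px, d.y_px) for d in dets]
        claimed = [False] * len(dets)

        # nearest in-reach detection per active track (deterministic ties:
        # smaller distance, then smaller (x, y))
        nearest = {}
        for tr in active:
            best = None
            for j, (dx, dy) in enumerate(positions):
                dist = float(np.hypot(dx - tr.xs[-1], dy - tr.ys[-1]))
                if dist <= dmax:
                    key = (dist, dx, dy)
                    if best is None or key < best[0]:
                        best = (key, j)
            if best is not None:
                nearest[tr.track_id] = (best[0][0], best[1])

        # conflictual tracking: two tracks sharing the same nearest
        # detection both stop; the detection stays unclaimed
        by_det = {}
        for tid, (dist, j) in nearest.items():
            by_det.setdefault(j, []).append(tid)
        conflicted = {tid for j, tids in by_det.items() if len(tids) > 1 for tid in tids}

        links = sorted(
            ((dist, tid, j) for tid, (dist, j) in nearest.items() if tid not in conflicted)
        )
        linked = set()
        for dist, tid, j in links:
            if claimed[j]:
                continue  # target taken by a closer track: treated as missing
            tr = next(t for t in active if t.track_id == tid)
            tr.append(f, *positions[j])
            claimed[j] = True
            linked.add(tid)

        still_active = []
        for tr in active:
            if tr.track_id in conflicted:
                finished.append(tr)
            elif tr.track_id in linked:
                still_active.append(tr)
            elif f - tr.last_frame >= gap:
                finished.append(tr)  # gap budget exhausted
            else:
                still_active.append(tr)  # missing tracking: gap pending
        active = still_active

        for j, d in enumerate(dets):
            if not claimed[j]:
                active.append(_ActiveTrack(next(ids), f, d.x_px, d.y_px))

    finished.extend(active)
    finished.sort(key=lambda t: t.track_id)
    return [
        Track(t.track_id, population, np.array(t.frames), np.array(t.xs), np.array(t.ys))
        for t in finished
    ]


def filter_tracks(tracks, min_duration=20):
    """Drop tracks spanning fewer than ``min_duration`` frames (inclusive)."""
    return [t for t in tracks if t.duration >= min_duration]


def _merge_pair(a: Track, b: Track) -> Track:
    """Concatenate two temporally disjoint tracks (a ends before b starts)."""
    return Track(
        a.track_id,
        a.population,
        np.concatenate([a.frames, b.frames]),
        np.concatenate([a.x, b.x]),
        np.concatenate([a.y, b.y]),
        provenance=sorted(set(a.provenance or [a.track_id]) | set(b.provenance or [b.track_id])),
    )


def merge_tracks(tracks, config):
    """Iteratively merge track fragments of one population to a fixed point.

    Tumor (cylindrical): fragments merge when the spatial distance between
    the earlier track's endpoint and the later track's start is within
    ``merge_radius_tumor``, for any temporal gap up to ``gap_tumor`` — a
    cylinder in (x, y, t).  Immune (spherical): merge when the combined
    spatio-temporal distance sqrt(dx^2 + dy^2 + (c*dframes)^2) is within
    ``merge_radius_immune`` with c = ``merge_time_scale``.  The closest
    admissible pair merges first; iteration continues until no pair
    qualifies.  Provenance records the source track ids.
    """
    if not tracks:
        return []
    pops = {t.population for t in tracks}
    if len(pops) > 1:
        raise ValueError("merge_tracks expects a single population")
    pop = pops.pop()
    work = [t.copy() for t in tracks]

    while True:
        best = None
        for i, a in enumerate(work):
            for j, b in enumerate(work):
                if i == j:
                    continue
                if a.frames[-1] >= b.frames[0]:
                    continue  # must stay temporally monotonic
                dt_frames = int(b.frames[0] - a.frames[-1])
                dx = b.x[0] - a.x[-1]
                dy = b.y[0] - a.y[-1]
                space = float(np.hypot(dx, dy))
                if pop == "tumor":
                    if dt_frames > config.gap_tumor or space > config.merge_radius_tumor:
                        continue
                    cost = space
                else:
                    cost = float(
                        np.sqrt(space**2 + (config.merge_time_scale * dt_frames) ** 2)
                    )
                    if cost > config.merge_radius_immune:
                        continue
                key = (cost, a.track_id, b.track_id)
                if best is None or key < best[0]:
                    best = (key, i, j)
        if best is None:
            break
        _, i, j = best
        merged = _merge_pair(work[i], work[j])
        work = [t for k, t in enumerate(work) if k not in (i, j)] + [merged]

    work.sort(key=lambda t: t.track_id)
    return work


def filter_roi(detections, roi_polygons, px_per_um=1.0):
    """Keep detections whose center lies inside at least one ROI polygon.

    Polygons are lists of ``(x, y)`` vertices in micrometres (chip
    coordinates, bottom-left origin); detections carry pixel coordinates and
    are converted via ``px_per_um``.  An empty polygon list keeps everything.
    """
    if not roi_polygons:
        return list(detections)
    if not detections:
        return []
    from matplotlib.path import Path as _MplPath

    pts = np.array([[d.x_px / px_per_um, d.y_px / px_per_um] for d in detections])
    keep = np.zeros(len(detections), dtype=bool)
    for poly in roi_polygons:
        keep |= _MplPath(np.asarray(poly, dtype=float)).contains_points(pts)
    return [d for d, k in zip(detections, keep) if k]


def track_stack(stack, config=None, px_per_um=1.0, roi_polygons=None,
                return_detections=False):
    """Full tracking pipeline on an image stack.

    Detect cells per frame over the union of the two populations' Hough
    radius ranges, discriminate by area, optionally mask to the ROI
    polygons (vertices in micrometres), link per population, drop short
    tracks and merge the surviving fragments.  Output coordinates are converted to
    micrometres via ``px_per_um``.  With ``return_detections`` the per-frame
    detections (after discrimination and ROI masking) are returned as well.
    """
    config = config or TrackingConfig()
    rmin = min(config.hough_radii_immune[0], config.hough_radii_tumor[0])
    rmax = max(config.hough_radii_immune[1], config.hough_radii_tumor[1])
    dets_by_frame = {}
    for f, img in enumerate(stack):
        dets = detect_cells(img, (rmin, rmax), config.sensitivity, frame=f)
        dets = discriminate(dets, config.area_threshold_px)
        dets_by_frame[f] = filter_roi(dets, roi_polygons, px_per_um)
    tracks = link_tracks(dets_by_frame, config)
    tracks = filter_tracks(tracks, config.min_duration)
    out = []
    for pop in ("immune", "tumor"):
        sub = merge_tracks([t for t in tracks if t.population == pop], config)
        out.extend(sub)
    for t in out:
        t.x = t.x / px_per_um
        t.y = t.y / px_per_um
    if return_detections:
        return out, dets_by_frame
    return out
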