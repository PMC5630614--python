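"""Effective chemoattractant potential landscape reconstruction.

Each tumor cell with at least one analyzed encounter is represented by a
truncated parabolic potential well centred on its position: the standard
parabolic (harmonic) approximation of a local equilibrium.  The well depth
is set by the strength of the local equilibrium — by default the basin
radius squared times the magnitude of the mean stable eigenvalue product —
and depths are normalized so the deepest well has relative depth 1.  The
full landscape is the pointwise minimum of the wells (locally, the deepest
signal prevails).  This is a heuristic visualization of the stability
results, not an inference of the true chemokine field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEPTH_POLICIES = ("eigen_radius", "radius", "captured")


@dataclass
class PotentialWell:
    tc_id: int
    center: tuple
    curvature: float  # 1/min^2 proxy from the mean stable eigenvalue product
    basin_radius: float
    depth: float  # un-normalized depth scale
    z_rel: float = np.nan  # depth normalized to the deepest well
    low_confidence: bool = False
    overlap_partners: list = field(default_factory=list)

    def potential(self, x, y):
        """U(x, y) = -z_rel * max(0, 1 - ||x - x0||^2 / R^2)."""
        d2 = (np.asarray(x) - self.center[0]) ** 2 + (np.asarray(y) - self.center[1]) ** 2
        return -self.z_rel * np.maximum(0.0, 1.0 - d2 / self.basin_radius**2)


def build_wells(results, attractors, depth_policy="eigen_radius"):
    """One parabolic well per tumor cell with analyzed encounters.

    Depth policies: ``eigen_radius`` (basin radius squared times the mean
    stable eigenvalue product, the curvature-times-size reading of "the
    larger the local equilibrium, the deeper the well"), ``radius`` (basin
    radius squared alone) and ``captured`` (number of PBMCs in the basin).
    A TC with only metastable encounters gets its curvature from |Re λ|
    magnitudes and is flagged low-confidence.
    """
    if depth_policy not in DEPTH_POLICIES:
        raise ValueError(f"unknown depth policy {depth_policy!r}")
    wells = []
    for att in attractors:
        here = [r for r in results if r.tc_id == att.tc_id and r.jacobian is not None]
        if not here:
            continue
        stable = [r for r in here if r.classification == "stable"]
        use = stable if stable else here
        prods = [
            abs(np.prod(np.abs(r.jacobian.eigenvalues.real))) for r in use
        ]
        curvature = float(np.mean(prods))
        radius = att.interaction_range or att.physical_interaction_range
        if depth_policy == "eigen_radius":
            depth = radius**2 * curvature
        elif depth_policy == "radius":
            depth = radius**2
        else:
            depth = float(len(att.basin_members))
        wells.append(
            PotentialWell(
                tc_id=att.tc_id,
                center=(att.x0, att.y0),
                curvature=curvature,
                basin_radius=float(radius),
                depth=float(depth),
                low_confidence=not stable,
            )
        )
    if not wells:
        return wells
    dmax = max(w.depth for w in wells)
    for w in wells:
        w.z_rel = w.depth / dmax if dmax > 0 else 1.0
    for i, a in enumerate(wells):
        for b in wells[i + 1 :]:
            dist = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
            if dist < a.basin_radius + b.basin_radius:
                a.overlap_partners.append(b.tc_id)
                b.overlap_partners.append(a.tc_id)
    return wells


def render_landscape(wells, x_grid, y_grid):
    """Pointwise-minimum potential surface on a rectangular grid.

    Returns an array of shape ``(len(y_grid), len(x_grid))``; zero outside
    every basin, down to ``-1`` at the deepest well's centre.
    """
    if not wells:
        raise ValueError("no wells to render")
    X, Y = np.meshgrid(np.asarray(x_grid), np.asarray(y_grid))
    surfaces = np.stack([w.potential(X, Y) for w in wells])
    return surfaces.min(axis=0)
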