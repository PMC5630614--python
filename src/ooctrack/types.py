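"""Core data containers shared by every pipeline stage.

The universal currency is the :class:`Track`: one cell's ordered positions
``(frame, x, y)`` in micrometres, with a population label (``"immune"`` or
``"tumor"``).  Coordinates use a bottom-left origin with y increasing upward;
pixel inputs are flipped on ingest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

POPULATIONS = ("immune", "tumor")


@dataclass
class Track:
    """One cell's trajectory.

    Parameters
    ----------
    track_id : int
        Identifier, unique within an ensemble.
    population : str
        ``"immune"`` or ``"tumor"``.
    frames : ndarray of int
        Strictly increasing frame indices.
    x, y : ndarray of float
        Positions in micrometres, origin bottom-left, y up.
    provenance : list of int
        Source track ids if this track was produced by merging.
    """

    track_id: int
    population: str
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.frames) == len(self.x) == len(self.y)):
            raise ValueError("frames, x, y must have equal length")
        if len(self.frames) > 1 and np.any(np.diff(self.frames) <= 0):
            raise ValueError(f"track {self.track_id}: frames not strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def duration(self) -> int:
        """Span in frames, inclusive of both endpoints."""
        return int(self.frames[-1] - self.frames[0] + 1)

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def copy(self) -> "Track":
        return replace(
            self,
            frames=self.frames.copy(),
            x=self.x.copy(),
            y=self.y.copy(),
            provenance=list(self.provenance),
        )


@dataclass
class Detection:
    """A single circle detection in one frame (pixel coordinates, y up)."""

    frame: int
    x_px: float
    y_px: float
    radius_px: float
    population: str = "unknown"

    @property
    def area_px(self) -> float:
        return float(np.pi * self.radius_px**2)
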