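"""Track and configuration I/O.

Tracks travel between stages as CSV with the header
``frame,cell_id,population,x_um,y_um`` (micrometres, origin bottom-left,
y up).  Configuration is YAML and round-trips losslessly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .stability import StabilityConfig
from .synth import RenderParams
from .tracking import TrackingConfig
from .types import POPULATIONS, Track

TRACK_COLUMNS = ["frame", "cell_id", "population", "x_um", "y_um"]


class SchemaError(ValueError):
    pass


def tracks_to_frame(tracks) -> pd.DataFrame:
    rows = []
    for t in tracks:
        for f, x, y in zip(t.frames, t.x, t.y):
            rows.append((int(f), int(t.track_id), t.population, float(x), float(y)))
    return pd.DataFrame(rows, columns=TRACK_COLUMNS)


def frame_to_tracks(df: pd.DataFrame):
    tracks = []
    for (cid, pop), g in df.groupby(["cell_id", "population"], sort=True):
        g = g.sort_values("frame")
        if g["frame"].duplicated().any():
            raise SchemaError(f"cell {cid}: duplicate frames")
        tracks.append(
            Track(int(cid), pop, g["frame"].to_numpy(), g["x_um"].to_numpy(), g["y_um"].to_numpy())
        )
    return tracks


def write_tracks(tracks, path):
    tracks_to_frame(tracks).to_csv(path, index=False)


def read_tracks(path):
    """Read a track CSV, validating schema and frame monotonicity."""
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    bad = ~df["population"].isin(POPULATIONS)
    if bad.any():
        line = int(df.index[bad][0]) + 2  # header + 1-based
        raise SchemaError(f"{path}: unknown population at line {line}")
    for col in ("frame", "cell_id", "x_um", "y_um"):
        if df[col].isna().any():
            line = int(df.index[df[col].isna()][0]) + 2
            raise SchemaError(f"{path}: malformed value in {col!r} at line {line}")
    try:
        return frame_to_tracks(df)
    except ValueError as e:
        raise SchemaError(f"{path}: {e}") from e


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, serializable to YAML."""

    dt_minutes: float = 2.0
    px_per_um: float = 1.0
    seed: int = 0
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    stability: StabilityConfig = field(default_factory=StabilityConfig)
    render: RenderParams = field(default_factory=RenderParams)
    turning_bins: int = 24
    fit_tie_threshold: float = 0.01
    depth_policy: str = "eigen_radius"
    roi_polygons: list = field(default_factory=list)

    def to_dict(self):
        def conv(v):
            if dataclasses.is_dataclass(v):
                return {k: conv(x) for k, x in dataclasses.asdict(v).items()}
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, tuple):
                return list(v)
            return v

        return {f.name: conv(getattr(self, f.name)) for f in dataclasses.fields(self)}

    def save(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path):
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data):
        data = dict(data)
        for key, sub in (
            ("tracking", TrackingConfig),
            ("stability", StabilityConfig),
            ("render", RenderParams),
        ):
            if key in data and isinstance(data[key], dict):
                d = dict(data[key])
                for fname in ("image_shape", "hough_radii_immune", "hough_radii_tumor"):
                    if fname in d and isinstance(d[fname], list):
                        d[fname] = tuple(d[fname])
                data[key] = sub(**d)
        return cls(**data)

    def config_hash(self) -> str:
        """Stable short hash of the full configuration, for run logs."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
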