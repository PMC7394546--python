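"""Reading and writing comet-track tables and neuron-geometry files.

Comet tracks arrive as delimited text in one of three dialects: the
package-native layout, ImageJ Manual Tracking exports, or TrackMate spot
exports.  Positions are converted from pixels to micrometres on read, and
every track is validated against the timing invariants of a single-Z-plane
movie (uniform frame interval, no gaps).  Neuron geometry — the soma
outline, optional nucleus, axon/dendrite entry points and Golgi stack
centres — is carried in a small YAML document.

Coordinates in files may use either the image convention (y increasing
downward, as exported by ImageJ) or the math convention (y increasing
upward).  All analysis in this package runs in the math convention; the
y-flip is applied explicitly on read, driven by the geometry file's
required ``y_axis`` field or by the ``y_axis`` argument for track tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Point, Polygon

logger = logging.getLogger(__name__)

_TIME_TOL = 1e-6  # s; tolerance on frame-interval uniformity


class TrackIOError(ValueError):
    """Malformed track table or geometry file."""


@dataclass(frozen=True)
class CometTrack:
    """One comet's time-ordered 2-D trajectory.

    ``points`` is an (n, 3) float array with columns (t [s], x [μm], y [μm]).
    """

    comet_id: str
    movie_id: str
    points: np.ndarray
    present_at_first_frame: bool = False
    frame_interval: float = 5.0

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise TrackIOError(
                f"track {self.comet_id}: needs >=2 (t, x, y) points, got shape {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise TrackIOError(f"track {self.comet_id}: non-finite coordinates")
        dt = np.diff(pts[:, 0])
        if np.any(dt <= 0):
            raise TrackIOError(f"track {self.comet_id}: time not strictly increasing")
        if np.any(np.abs(dt - self.frame_interval) > _TIME_TOL):
            bad = int(np.argmax(np.abs(dt - self.frame_interval) > _TIME_TOL))
            raise TrackIOError(
                f"track {self.comet_id}: frame gap between points {bad} and {bad + 1} "
                f"(dt={dt[bad]:g} s, expected {self.frame_interval:g} s)"
            )

    @property
    def xy(self) -> np.ndarray:
        return self.points[:, 1:3]

    @property
    def t(self) -> np.ndarray:
        return self.points[:, 0]


@dataclass(frozen=True)
class GolgiStack:
    name: str
    center: np.ndarray
    association_radius: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.association_radius <= 0:
            raise TrackIOError(f"golgi stack {self.name}: association_radius must be > 0")


@dataclass(frozen=True)
class NeuronGeometry:
    """Spatial frame of a single neuron soma, in math-convention μm.

    ``dendrite_branchpoints`` marks, per dendrite, the end of the proximal
    segment ("before any branches") used for polarity scoring.
    """

    soma: Polygon
    axon_entry: np.ndarray
    dendrite_entries: dict[str, np.ndarray]
    golgi_stacks: tuple[GolgiStack, ...] = ()
    nucleus: Optional[Polygon] = None
    dendrite_branchpoints: dict[str, np.ndarray] = field(default_factory=dict)
    frame_interval: float = 5.0

    def __post_init__(self):
        object.__setattr__(self, "axon_entry", np.asarray(self.axon_entry, dtype=float))
        object.__setattr__(
            self,
            "dendrite_entries",
            {k: np.asarray(v, dtype=float) for k, v in self.dendrite_entries.items()},
        )
        object.__setattr__(
            self,
            "dendrite_branchpoints",
            {k: np.asarray(v, dtype=float) for k, v in self.dendrite_branchpoints.items()},
        )
        soma = self.soma
        if len(soma.exterior.coords) - 1 < 3:
            raise TrackIOError("soma polygon needs at least 3 vertices")
        if not soma.is_simple or not soma.is_valid:
            raise TrackIOError("soma polygon is self-intersecting")
        if self.nucleus is not None and not soma.contains(self.nucleus):
            raise TrackIOError("nucleus not contained within soma")
        for name, pt in [("axon", self.axon_entry)] + list(self.dendrite_entries.items()):
            d = soma.exterior.distance(Point(pt))
            if d > 1.0:
                raise TrackIOError(
                    f"entry point {name!r} is {d:.2f} μm from the soma boundary (>1 μm)"
                )
        if self.frame_interval <= 0:
            raise TrackIOError("frame_interval must be > 0")

    def entry_point(self, neurite_name: str) -> np.ndarray:
        if neurite_name == "axon":
            return self.axon_entry
        try:
            return self.dendrite_entries[neurite_name]
        except KeyError:
            raise KeyError(f"unknown neurite {neurite_name!r}") from None

    @property
    def neurite_names(self) -> list[str]:
        return ["axon"] + sorted(self.dendrite_entries)


_DIALECTS = {
    "native": {"track": "comet_id", "movie": "movie_id", "frame": "frame",
               "x": "x_px", "y": "y_px", "first_frame": 0},
    "manual_tracking": {"track": "Track n°", "movie": None, "frame": "Slice n°",
                        "x": "X", "y": "Y", "first_frame": 1},  # slices are 1-based
    "trackmate": {"track": "TRACK_ID", "movie": None, "frame": "FRAME",
                  "x": "POSITION_X", "y": "POSITION_Y", "first_frame": 0},
}


def read_tracks(
    path,
    dialect: str = "native",
    frame_interval: float = 5.0,
    pixel_size: float = 0.1,
    y_axis: str = "math",
) -> list[CometTrack]:
    """Read a delimited comet-track table into validated :class:`CometTrack`s.

    Positions are scaled by ``pixel_size`` (μm/px).  A track is flagged
    ``present_at_first_frame`` when its first row sits at the dialect's first
    frame index (0, or 1 for 1-based Manual Tracking slices).  Output is
    sorted by (movie_id, comet_id).
    """
    if dialect not in _DIALECTS:
        raise TrackIOError(f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECTS)}")
    if pixel_size <= 0 or frame_interval <= 0:
        raise TrackIOError("pixel_size and frame_interval must be > 0")
    if y_axis not in ("math", "image"):
        raise TrackIOError(f"y_axis must be 'math' or 'image', got {y_axis!r}")
    path = Path(path)
    cols = _DIALECTS[dialect]
    sep = "\t" if dialect == "manual_tracking" else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in (cols["track"], cols["frame"], cols["x"], cols["y"])
               if c not in df.columns]
    if missing:
        raise TrackIOError(f"{path.name}: missing required columns {missing}")
    zcols = [c for c in df.columns if c.lower() in ("z", "z_px", "position_z")]
    if zcols:
        logger.warning("%s: ignoring z column(s) %s (single Z-plane analysis)", path.name, zcols)
    out_rows = pd.DataFrame({
        "comet_id": df[cols["track"]].astype(str),
        "movie_id": (df[cols["movie"]].astype(str) if cols["movie"] else path.stem),
        "frame": df[cols["frame"]].astype(int),
        "x": df[cols["x"]].astype(float) * pixel_size,
        "y": df[cols["y"]].astype(float) * pixel_size,
    })
    if y_axis == "image":
        out_rows["y"] = -out_rows["y"]
    dup = out_rows.duplicated(subset=["movie_id", "comet_id", "frame"])
    if dup.any():
        rows = (np.flatnonzero(dup.to_numpy()) + 2).tolist()  # 1-based + header
        raise TrackIOError(f"{path.name}: duplicate (track, frame) rows at file rows {rows}")

    tracks = []
    for (movie_id, comet_id), grp in out_rows.groupby(["movie_id", "comet_id"], sort=True):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy()
        movie_first = cols["first_frame"]
        gaps = np.flatnonzero(np.diff(frames) != 1)
        if gaps.size:
            g = gaps[0]
            raise TrackIOError(
                f"{path.name}: track {comet_id} has a frame gap between "
                f"frames {frames[g]} and {frames[g + 1]}"
            )
        pts = np.column_stack([frames * frame_interval, grp["x"], grp["y"]])
        tracks.append(CometTrack(
            comet_id=str(comet_id),
            movie_id=str(movie_id),
            points=pts,
            present_at_first_frame=bool(frames[0] == movie_first),
            frame_interval=frame_interval,
        ))
    return tracks


def write_tracks(tracks, path, pixel_size: float = 0.1) -> None:
    """Serialize tracks as a native-dialect CSV (inverse of :func:`read_tracks`)."""
    if pixel_size <= 0:
        raise TrackIOError("pixel_size must be > 0")
    rows = []
    for tr in tracks:
        frames = np.rint(tr.t / tr.frame_interval).astype(int)
        for f, (x, y) in zip(frames, tr.xy):
            rows.append((tr.comet_id, tr.movie_id, f, x / pixel_size, y / pixel_size))
    df = pd.DataFrame(rows, columns=["comet_id", "movie_id", "frame", "x_px", "y_px"])
    df.to_csv(path, index=False, float_format="%.12g")


def filter_first_frame(tracks: list[CometTrack]) -> list[CometTrack]:
    """Drop tracks already present at the movie's first timepoint.

    Comets present in the first frame may be pre-existing microtubules
    rather than new growth events, so they are excluded from all analyses.
    """
    kept = [tr for tr in tracks if not tr.present_at_first_frame]
    removed = len(tracks) - len(kept)
    if removed:
        logger.info("filter_first_frame: removed %d of %d tracks", removed, len(tracks))
    if tracks and not kept:
        logger.warning("filter_first_frame: all %d tracks started at frame 0", len(tracks))
    return kept


def _poly_coords(poly: Polygon) -> list[list[float]]:
    return [[float(x), float(y)] for x, y in list(poly.exterior.coords)[:-1]]


def read_geometry(path) -> NeuronGeometry:
    """Read a neuron-geometry YAML document; all invariants are enforced."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise TrackIOError(f"{path.name}: not a mapping document")
    try:
        y_axis = doc["y_axis"]
        soma_raw = doc["soma"]
    except KeyError as exc:
        raise TrackIOError(f"{path.name}: missing required key {exc}") from None
    if y_axis not in ("math", "image"):
        raise TrackIOError(f"{path.name}: y_axis must be 'math' or 'image'")
    flip = -1.0 if y_axis == "image" else 1.0

    def pt(p):
        return np.array([float(p[0]), flip * float(p[1])])

    soma_pts = [pt(p) for p in soma_raw]
    if len(soma_pts) < 3:
        raise TrackIOError(f"{path.name}: soma polygon has fewer than 3 vertices")
    nucleus = None
    if doc.get("nucleus"):
        nucleus = Polygon([pt(p) for p in doc["nucleus"]])
    stacks = tuple(
        GolgiStack(name=str(k), center=pt(v["center"]),
                   association_radius=float(v.get("radius", 1.0)))
        for k, v in sorted((doc.get("golgi_stacks") or {}).items())
    )
    return NeuronGeometry(
        soma=Polygon(soma_pts),
        nucleus=nucleus,
        axon_entry=pt(doc["axon_entry"]),
        dendrite_entries={str(k): pt(v) for k, v in (doc.get("dendrite_entries") or {}).items()},
        dendrite_branchpoints={str(k): pt(v)
                               for k, v in (doc.get("dendrite_branchpoints") or {}).items()},
        golgi_stacks=stacks,
        frame_interval=float(doc.get("frame_interval_s", 5.0)),
    )


def write_geometry(geom: NeuronGeometry, path) -> None:
    """Serialize geometry as YAML in the math convention."""
    doc = {
        "y_axis": "math",
        "frame_interval_s": float(geom.frame_interval),
        "soma": _poly_coords(geom.soma),
        "nucleus": _poly_coords(geom.nucleus) if geom.nucleus is not None else None,
        "axon_entry": [float(v) for v in geom.axon_entry],
        "dendrite_entries": {k: [float(x) for x in v] for k, v in geom.dendrite_entries.items()},
        "dendrite_branchpoints": {k: [float(x) for x in v]
                                  for k, v in geom.dendrite_branchpoints.items()},
        "golgi_stacks": {s.name: {"center": [float(x) for x in s.center],
                                  "radius": float(s.association_radius)}
                         for s in geom.golgi_stacks},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, default_flow_style=None)
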