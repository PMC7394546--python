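"""Angular and spatial primitives for comet-track analysis.

The central measurement is the initial growth angle of a comet relative to
the axon entry site: the angle, at the comet's origin, between the ray from
the origin to the axon entry point and the comet's initial direction of
growth.  Angles are signed in (−180, 180], positive counterclockwise in
math-convention coordinates, and are "folded" to [0, 180] by taking the
absolute value when left/right of the axon should not be distinguished.

Also here: construction of the ~0.5 μm entry zone spanning a neurite mouth,
assignment of comet origins to Golgi stacks, and distances to the cell
cortex / nuclear envelope used by the turning rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
from shapely.geometry import LineString, Point, Polygon

from .track_io import CometTrack, NeuronGeometry

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GrowthAngle:
    comet_id: str
    theta_signed: float  # degrees in (-180, 180]
    theta_folded: float  # degrees in [0, 180]
    origin_stack: Optional[str] = None


class CortexDistance(NamedTuple):
    soma: float
    nucleus: Optional[float]


@dataclass(frozen=True)
class EntryZone:
    """The ~0.5 μm wide band across a neurite entrance.

    ``inner_gate`` / ``outer_gate`` are 2×2 arrays of segment endpoints;
    the outer gate is the one on the neurite side of the entrance.  A comet
    touching the band has *approached*; one crossing the outer gate has
    *entered*.
    """

    neurite_name: str
    kind: str  # "axon" | "dendrite"
    inner_gate: np.ndarray
    outer_gate: np.ndarray
    width: float

    @property
    def band(self) -> Polygon:
        a, b = self.inner_gate
        c, d = self.outer_gate
        return Polygon([a, b, d, c])

    @property
    def center(self) -> np.ndarray:
        return (self.inner_gate.mean(axis=0) + self.outer_gate.mean(axis=0)) / 2.0

    @property
    def outward_normal(self) -> np.ndarray:
        n = self.outer_gate.mean(axis=0) - self.inner_gate.mean(axis=0)
        return n / np.linalg.norm(n)

    @property
    def outer_gate_line(self) -> LineString:
        return LineString(self.outer_gate)


def fold_angle(theta_signed: float) -> float:
    """Map a signed angle in (−180, 180] to [0, 180] by |θ|.

    Comets growing to the left or right of the axon at the same inclination
    are not distinguished.
    """
    if not (-180.0 < theta_signed <= 180.0 + 1e-12):
        raise ValueError(f"theta_signed {theta_signed} out of (-180, 180]")
    return abs(float(theta_signed))


def _signed_angle_deg(ref: np.ndarray, vec: np.ndarray) -> float:
    """Signed angle from ``ref`` to ``vec``, CCW positive, in (−180, 180]."""
    ang = np.degrees(np.arctan2(ref[0] * vec[1] - ref[1] * vec[0], ref @ vec))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def _tls_direction(pts: np.ndarray) -> np.ndarray:
    """Total-least-squares direction of points, oriented by net displacement."""
    net = pts[-1] - pts[0]
    norm = np.linalg.norm(net)
    if norm < 1e-12:
        raise ValueError("zero net displacement: initial direction undefined")
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    v = vt[0]
    if v @ net < 0:
        v = -v
    return v / np.linalg.norm(v)


def assign_origin_stack(origin: np.ndarray, geometry: NeuronGeometry) -> Optional[str]:
    """Nearest Golgi stack within its association radius, else None.

    Exact distance ties resolve to the lexicographically first stack name.
    """
    best = None
    for s in sorted(geometry.golgi_stacks, key=lambda s: s.name):
        d = float(np.linalg.norm(origin - s.center))
        if d > s.association_radius:
            continue
        if best is None or d < best[0]:
            best = (d, s.name)
        elif d == best[0]:
            logger.info("origin equidistant from stacks %s and %s; keeping %s",
                        best[1], s.name, best[1])
    return None if best is None else best[1]


def initial_growth_angle(
    track: CometTrack,
    geometry: NeuronGeometry,
    n_direction_points: int = 3,
) -> GrowthAngle:
    """Initial growth angle of a comet relative to the axon entry site.

    The initial direction is the total-least-squares line through the first
    ``n_direction_points`` positions, oriented by their net displacement.
    θ is measured at the comet origin from the ray (origin → axon entry) to
    that direction, CCW positive.
    """
    if len(track.points) < n_direction_points:
        raise ValueError(
            f"track {track.comet_id}: {len(track.points)} points < "
            f"n_direction_points={n_direction_points}"
        )
    origin = track.xy[0]
    if not geometry.soma.covers(Point(origin)):
        raise ValueError(f"track {track.comet_id}: origin lies outside the soma")
    direction = _tls_direction(track.xy[:n_direction_points])
    ray = geometry.axon_entry - origin
    if np.linalg.norm(ray) < 1e-12:
        raise ValueError(f"track {track.comet_id}: origin coincides with the axon entry site")
    theta = _signed_angle_deg(ray, direction)
    return GrowthAngle(
        comet_id=track.comet_id,
        theta_signed=theta,
        theta_folded=fold_angle(theta),
        origin_stack=assign_origin_stack(origin, geometry),
    )


def _boundary_normal(geometry: NeuronGeometry, point: np.ndarray) -> np.ndarray:
    """Outward unit normal of the soma-boundary edge nearest to ``point``."""
    coords = np.asarray(geometry.soma.exterior.coords)
    p = Point(point)
    best_d, best_edge = np.inf, None
    for i in range(len(coords) - 1):
        seg = LineString([coords[i], coords[i + 1]])
        d = seg.distance(p)
        if d < best_d:
            best_d, best_edge = d, (coords[i], coords[i + 1])
    if best_edge is None:
        raise ValueError("cannot resolve a boundary normal: degenerate soma polygon")
    a, b = best_edge
    e = b - a
    n = np.array([e[1], -e[0]])
    n /= np.linalg.norm(n)
    mid = (a + b) / 2.0
    probe = mid + 1e-6 * n
    if geometry.soma.covers(Point(probe)):  # flip if pointing inward
        n = -n
    return n


def build_entry_zone(
    geometry: NeuronGeometry,
    neurite_name: str,
    width: float = 0.5,
    caliber: float = 2.0,
) -> EntryZone:
    """Construct the entry zone across a neurite mouth.

    Gates are perpendicular to the local neurite axis, estimated as the
    outward soma-boundary normal at the entry point; they are centred on
    the entry point, span ``caliber`` μm (clamped to [1, 5]) across the
    mouth, and sit ``width``/2 either side of it.
    """
    if width <= 0:
        raise ValueError("entry-zone width must be > 0")
    entry = geometry.entry_point(neurite_name)
    kind = "axon" if neurite_name == "axon" else "dendrite"
    n = _boundary_normal(geometry, entry)
    t = np.array([-n[1], n[0]])
    half = np.clip(caliber, 1.0, 5.0) / 2.0
    inner_c = entry - (width / 2.0) * n
    outer_c = entry + (width / 2.0) * n
    return EntryZone(
        neurite_name=neurite_name,
        kind=kind,
        inner_gate=np.array([inner_c - half * t, inner_c + half * t]),
        outer_gate=np.array([outer_c - half * t, outer_c + half * t]),
        width=float(width),
    )


def distance_to_cortex(point, geometry: NeuronGeometry) -> CortexDistance:
    """Distance from an interior point to the soma boundary (and nucleus, if any)."""
    p = Point(np.asarray(point, dtype=float))
    if not geometry.soma.covers(p):
        raise ValueError(f"point {tuple(np.asarray(point))} lies outside the soma")
    d_soma = float(geometry.soma.exterior.distance(p))
    d_nuc = (float(geometry.nucleus.exterior.distance(p))
             if geometry.nucleus is not None else None)
    return CortexDistance(soma=d_soma, nucleus=d_nuc)
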