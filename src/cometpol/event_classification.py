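"""Per-comet event classification: approach, entry, turning, polarity.

A comet originating in the soma *approaches* a neurite when its path
touches that neurite's entry zone (the ~0.5 μm band across the mouth), and
*enters* when it subsequently crosses the outer gate of that band into the
neurite.  Turning is scored only on comets that grew more than 2 μm within
the soma and did not travel along the cell cortex, since direction changes
at the cortex or nuclear envelope are collisions rather than guided turns.
Within a proximal dendrite segment, the sign of a comet's net displacement
along the dendrite axis classifies it as anterograde (plus-end-out proxy)
or retrograde (minus-end-out proxy).

All thresholds live in :class:`TurningParams` / function defaults and are
reported in run manifests: these events are traditionally scored by eye,
so a reproducible pipeline needs every rule to be explicit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Point

from .geometry import EntryZone, _boundary_normal
from .track_io import CometTrack, NeuronGeometry

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TurningParams:
    """Operational definition of a turning event.

    min_path_length: μm of within-soma growth required to qualify.
    turn_angle_threshold: degrees of cumulative direction change that count
        as a turn.
    smoothing_window: frames per direction estimate (smooths localisation
        jitter).
    cortex_margin: μm; points closer than this to the soma boundary (or the
        nucleus) are treated as cortex/nuclear-envelope territory.
    """

    min_path_length: float = 2.0
    turn_angle_threshold: float = 45.0
    smoothing_window: int = 3
    cortex_margin: float = 1.0
    collinearity_tol: float = 5.0  # deg; sharper per-step bends end a window

    def __post_init__(self):
        if min(self.min_path_length, self.turn_angle_threshold,
               self.smoothing_window, self.cortex_margin,
               self.collinearity_tol) <= 0:
            raise ValueError("all turning parameters must be positive")
        if not (0 < self.turn_angle_threshold < 180):
            raise ValueError("turn_angle_threshold must be in (0, 180)")


@dataclass(frozen=True)
class CometEvents:
    """Classification record for one comet."""

    comet_id: str
    origin_region: str = "soma"  # soma | proximal_dendrite | other
    approached: Optional[str] = None  # first zone contacted
    approached_all: tuple[str, ...] = ()
    entered: Optional[str] = None
    qualifies_for_turning: bool = False
    turned: bool = False
    cortex_traveller: bool = False
    dendrite_polarity: Optional[str] = None  # anterograde | retrograde
    excluded_origin_in_zone: bool = False

    def __post_init__(self):
        if self.entered is not None and self.entered not in self.approached_all:
            raise ValueError("a comet can only enter a neurite it approached")
        if self.turned and not self.qualifies_for_turning:
            raise ValueError("turned implies qualifies_for_turning")


class ApproachEntry(NamedTuple):
    approached: Optional[str]
    entered: Optional[str]
    approached_all: tuple[str, ...]


def validate_zones(zones) -> None:
    """Entry-zone bands must not overlap, or a crossing would be ambiguous."""
    zones = list(zones)
    for i, a in enumerate(zones):
        for b in zones[i + 1:]:
            if a.band.intersects(b.band):
                raise ValueError(
                    f"entry zones {a.neurite_name!r} and {b.neurite_name!r} overlap"
                )


def origin_in_zone(track: CometTrack, zones) -> Optional[str]:
    """Name of the zone containing the comet origin, if any (such comets are
    excluded from approach/entry denominators)."""
    p = Point(track.xy[0])
    for z in zones:
        if z.band.covers(p):
            return z.neurite_name
    return None


def classify_approach_entry(
    track: CometTrack,
    zones,
    geometry: NeuronGeometry,
) -> ApproachEntry:
    """Score which entry zones a comet touched and whether it entered one.

    ``approached_all`` lists every zone whose band the path touched, in
    order of first contact; ``entered`` is the zone whose outer gate the
    path subsequently crossed (classification stops there — beyond the
    outer gate the comet is inside the neurite).
    """
    zones = list(zones)
    validate_zones(zones)
    if not geometry.soma.covers(Point(track.xy[0])):
        raise ValueError(f"track {track.comet_id}: origin outside the soma")
    approached: list[str] = []
    entered: Optional[str] = None
    xy = track.xy
    for i in range(len(xy) - 1):
        seg = LineString([xy[i], xy[i + 1]])
        hit = [z for z in zones if z.band.intersects(seg)]
        hit.sort(key=lambda z: Point(xy[i]).distance(z.band))
        for z in hit:
            if z.neurite_name not in approached:
                approached.append(z.neurite_name)
        for z in hit:
            if seg.intersects(z.outer_gate_line):
                # crossed the outer gate leaving the soma side
                entered = z.neurite_name
                break
        if entered:
            break
    return ApproachEntry(
        approached=approached[0] if approached else None,
        entered=entered,
        approached_all=tuple(approached),
    )


def _within_soma_prefix(xy: np.ndarray, geometry: NeuronGeometry) -> np.ndarray:
    inside = shapely.intersects_xy(geometry.soma, xy[:, 0], xy[:, 1])
    if not inside[0]:
        return xy[:0]
    stop = np.argmin(inside) if not inside.all() else len(xy)
    return xy[:stop]


def detect_turning(
    track: CometTrack,
    geometry: NeuronGeometry,
    params: TurningParams = TurningParams(),
) -> tuple[bool, bool, bool]:
    """Return (qualifies, turned, cortex_traveller) for one comet.

    A comet qualifies when its within-soma path exceeds
    ``params.min_path_length`` and it is not a cortex traveller (at least
    half of its within-soma points hugging the boundary).  It turned when
    two direction estimates, smoothed over ``params.smoothing_window``
    frames and separated along the path, differ by at least the angle
    threshold, with the sharpest intervening vertex lying farther than
    ``params.cortex_margin`` from both the soma boundary and the nucleus —
    direction changes at those boundaries are collisions, not turns.
    """
    xy = _within_soma_prefix(track.xy, geometry)
    m = len(xy)
    if m < 2:
        logger.info("track %s: fewer than 2 within-soma points; not qualifying",
                    track.comet_id)
        return False, False, False
    steps = np.diff(xy, axis=0)
    path_len = float(np.linalg.norm(steps, axis=1).sum())
    pts_geom = shapely.points(xy)
    d_cortex = shapely.distance(pts_geom, geometry.soma.exterior)
    cortex_traveller = bool(np.sum(d_cortex <= params.cortex_margin) >= 0.5 * m)
    qualifies = path_len > params.min_path_length and not cortex_traveller
    if m < params.smoothing_window:
        logger.info("track %s: %d points < smoothing window %d; not qualifying",
                    track.comet_id, m, params.smoothing_window)
        return False, False, cortex_traveller
    if not qualifies:
        return False, False, cortex_traveller

    # per-interior-point step direction change, for locating the vertex
    step_n = np.linalg.norm(steps, axis=1)
    valid = (step_n[:-1] > 1e-12) & (step_n[1:] > 1e-12)
    cosv = np.einsum("ij,ij->i", steps[:-1], steps[1:]) / np.where(
        valid, step_n[:-1] * step_n[1:], 1.0)
    step_change = np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0)))
    step_change[~valid] = 0.0  # change at point k uses step_change[k-1]

    w = params.smoothing_window
    # window direction estimates: one window per step index, truncated at the
    # track end and at sharp vertices (so a clear direction change is never
    # averaged away), plus start-truncated windows so a change right after
    # the first frame is resolvable
    sharp = np.flatnonzero(step_change > params.collinearity_tol) + 1  # vertex indices
    starts, ends_l = [], []
    for i in range(m - 1):
        nxt = sharp[np.searchsorted(sharp, i + 1)] if np.searchsorted(sharp, i + 1) < len(sharp) else m - 1
        starts.append(i)
        ends_l.append(min(i + w - 1, m - 1, int(nxt)))
    for e in range(1, min(w - 1, m)):
        starts.append(0)
        ends_l.append(e)
    win = sorted(set(zip(starts, ends_l)))
    starts = np.array([s for s, _ in win])
    ends = np.array([e for _, e in win])
    dirs = xy[ends] - xy[starts]
    norms = np.linalg.norm(dirs, axis=1)
    ok = norms > 1e-12
    unit = np.where(ok[:, None], dirs / np.where(ok, norms, 1.0)[:, None], 0.0)

    d_nuc = (shapely.distance(pts_geom, geometry.nucleus.exterior)
             if geometry.nucleus is not None else np.full(m, np.inf))
    vertex_ok = (d_cortex > params.cortex_margin) & (d_nuc > params.cortex_margin)
    cos_thresh = np.cos(np.radians(params.turn_angle_threshold))
    cosmat = unit @ unit.T
    cand = np.argwhere(np.triu(cosmat <= cos_thresh, k=1) & np.outer(ok, ok))
    for i, j in cand:
        lo = min(starts[i], starts[j]) + 1
        hi = max(ends[i], ends[j])  # interior points spanned by the window pair
        ks = np.arange(lo, hi)
        ks = ks[(ks >= 1) & (ks <= m - 2)]
        if ks.size == 0:
            continue
        k = int(ks[np.argmax(step_change[ks - 1])])
        if vertex_ok[k]:
            return True, True, cortex_traveller
    return True, False, cortex_traveller


def dendrite_axis(geometry: NeuronGeometry, dendrite_name: str) -> tuple[np.ndarray, np.ndarray, float]:
    """(entry, unit axis pointing distally, proximal segment length)."""
    entry = geometry.entry_point(dendrite_name)
    branch = geometry.dendrite_branchpoints.get(dendrite_name)
    if branch is None:
        branch = entry + 10.0 * _boundary_normal(geometry, entry)
    axis = branch - entry
    length = float(np.linalg.norm(axis))
    if length < 1e-9:
        raise ValueError(f"dendrite {dendrite_name!r}: degenerate proximal segment")
    return entry, axis / length, length


def classify_dendrite_polarity(
    track: CometTrack,
    geometry: NeuronGeometry,
    dendrite_name: str,
    zone_width: float = 0.5,
    halfwidth: float = 1.0,
    noise_floor: float = 0.2,
) -> Optional[str]:
    """Anterograde/retrograde call within a proximal dendrite segment.

    The segment runs from the entry zone's outer gate to the dendrite's
    branchpoint marker.  Net displacement projected on the dendrite axis
    decides the call; magnitudes below ``noise_floor`` μm are indeterminate
    (None, logged) and are excluded from polarity denominators.
    """
    entry, u, seg_len = dendrite_axis(geometry, dendrite_name)
    rel = track.xy - entry
    s = rel @ u
    lateral = np.abs(rel @ np.array([-u[1], u[0]]))
    in_segment = (s >= zone_width / 2.0) & (s <= seg_len) & (lateral <= halfwidth)
    idx = np.flatnonzero(in_segment)
    if idx.size < 2:
        raise ValueError(
            f"track {track.comet_id}: fewer than 2 points inside the proximal "
            f"segment of dendrite {dendrite_name!r}"
        )
    net = float(s[idx[-1]] - s[idx[0]])
    if abs(net) < noise_floor:
        logger.info("track %s: net dendrite displacement %.3g μm below noise floor; "
                    "indeterminate", track.comet_id, net)
        return None
    return "anterograde" if net > 0 else "retrograde"


def _prop_row(metric: str, k: int, n: int) -> dict:
    from . import inference_stats
    if n == 0:
        logger.warning("tabulate_events: metric %s has zero denominator", metric)
        return {"metric": metric, "k": k, "n": 0, "percent": np.nan,
                "ci_low": np.nan, "ci_high": np.nan, "defined": False}
    p = inference_stats.proportion(k, n)
    return {"metric": metric, "k": p.k, "n": p.n, "percent": p.percent,
            "ci_low": p.ci_low, "ci_high": p.ci_high, "defined": True}


def tabulate_events(events) -> pd.DataFrame:
    """Summarise classified comets into the standard report rows.

    Approach percentages are over soma-origin comets; entry percentages
    both over approachers of that neurite and over all soma-origin comets;
    turning over qualifying comets; polarity over determinate dendrite
    comets.  Each row carries k, n, percent and a Wilson 95% CI.
    """
    events = list(events)
    soma = [e for e in events if e.origin_region == "soma" and not e.excluded_origin_in_zone]
    n_soma = len(soma)

    def is_dendrite(name):
        return name is not None and name != "axon"

    app_ax = sum("axon" in e.approached_all for e in soma)
    app_de = sum(any(is_dendrite(a) for a in e.approached_all) for e in soma)
    ent_ax = sum(e.entered == "axon" for e in soma)
    ent_de = sum(is_dendrite(e.entered) for e in soma)
    n_qual = sum(e.qualifies_for_turning for e in soma)
    n_turn = sum(e.turned for e in soma)
    polar = [e.dendrite_polarity for e in events if e.dendrite_polarity is not None]
    n_polar = len(polar)
    n_antero = sum(p == "anterograde" for p in polar)

    rows = [
        _prop_row("approached_axon", app_ax, n_soma),
        _prop_row("approached_dendrite", app_de, n_soma),
        _prop_row("entered_axon_of_approached", ent_ax, app_ax),
        _prop_row("entered_dendrite_of_approached", ent_de, app_de),
        _prop_row("entered_axon_of_all", ent_ax, n_soma),
        _prop_row("entered_dendrite_of_all", ent_de, n_soma),
        _prop_row("turned_of_qualifying", n_turn, n_qual),
        _prop_row("anterograde_in_dendrite", n_antero, n_polar),
        _prop_row("retrograde_in_dendrite", n_polar - n_antero, n_polar),
    ]
    return pd.DataFrame(rows)
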