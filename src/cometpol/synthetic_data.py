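"""Synthetic comet tracks with ground-truth labels.

Two generators live here.  :func:`simulate_neuron` draws stochastic comet
trajectories with the statistical structure the analysis assumes: comets
nucleate at Golgi stacks with a von Mises bias of their initial angle
toward the axon entry site (κ = 0 recovers the uniform null), grow as
straight-segment walks with occasional guided turns that redirect growth
toward the axon, reflect off the cell cortex and nuclear envelope, and on
touching a neurite entry zone pass a single Bernoulli gate that decides
entry versus rejection.  Every comet carries a :class:`GroundTruth` record
of what actually happened, so classification can be scored against truth.

:func:`fixture_counts` instead builds fully deterministic piecewise-linear
tracks whose classified counts exactly equal a requested table — the tool
for reproducing published percentages without raw microscopy data.

This is a phenomenological generator, not a force model: guidance is a
redirection rule, not an explicit rail-microtubule simulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from shapely.geometry import LineString, Polygon

from .event_classification import TurningParams
from .geometry import EntryZone, build_entry_zone
from .track_io import CometTrack, GolgiStack, NeuronGeometry

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeometrySpec:
    """Parametric soma: an ellipse with entry points on its boundary.

    Defaults give a ~12 x 10 μm soma with one axon, two primary dendrites
    and 8 Golgi stacks (the observed per-neuron stack count is ~8-9).
    """

    soma_axes: tuple[float, float] = (6.0, 5.0)
    nucleus_fraction: float = 0.55  # 0 disables the nucleus
    axon_angle_deg: float = 90.0
    dendrite_angles_deg: tuple[float, ...] = (210.0, 330.0)
    n_golgi: int = 8
    golgi_radius: float = 1.0
    n_boundary_vertices: int = 256
    dendrite_length: float = 10.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the stochastic generator.

    Kinetics (0.1 μm/s growth, 5 s frames, 0.005/s catastrophe hazard) give
    tracks of a few μm over tens of frames.  Entry gates default to the
    control-like rates p_enter_axon = 0.54 and p_enter_dendrite = 0.28, and
    the nucleation bias to κ = 3.
    """

    geometry: GeometrySpec = field(default_factory=GeometrySpec)
    kappa_nucleation: float = 3.0
    frac_golgi_origin: float = 0.5
    growth_speed: float = 0.1  # μm/s
    frame_interval: float = 5.0  # s
    catastrophe_rate: float = 0.005  # per s
    p_turn_per_frame: float = 0.05
    turn_jitter_kappa: float = 8.0
    p_enter_axon: float = 0.54
    p_enter_dendrite: float = 0.28
    position_noise_sd: float = 0.05  # μm
    n_comets: int = 51
    seed: int = 0
    max_frames: int = 240
    zone_width: float = 0.5
    zone_caliber: float = 2.0

    def __post_init__(self):
        for p in (self.frac_golgi_origin, self.p_turn_per_frame,
                  self.p_enter_axon, self.p_enter_dendrite):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if min(self.growth_speed, self.frame_interval) <= 0:
            raise ValueError("growth_speed and frame_interval must be > 0")
        if self.kappa_nucleation < 0 or self.catastrophe_rate < 0:
            raise ValueError("rates and concentrations must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """What actually happened to one simulated comet."""

    comet_id: str
    origin_stack: Optional[str]
    true_initial_angle: float  # signed degrees relative to the axon ray
    turn_frames: tuple[int, ...]  # sample indices of guided turns
    gate_contacted: Optional[str]
    gate_outcome: Optional[str]  # entered | rejected
    termination_cause: str  # catastrophe | gate_rejected | entered | max_frames
    qualifies_for_turning: bool
    turned: bool
    cortex_traveller: bool


def _ellipse_polygon(a: float, b: float, n: int) -> np.ndarray:
    # circumscribe slightly so every point of the true ellipse is inside
    scale = 1.0 / np.cos(np.pi / n)
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack([a * scale * np.cos(th), b * scale * np.sin(th)])


def _edge_midpoint_near(verts: np.ndarray, a: float, b: float, angle_deg: float) -> np.ndarray:
    """Midpoint of the boundary edge nearest the given parametric angle.

    Entry points sit at edge midpoints so the discretised boundary normal
    there coincides with the analytic ellipse normal.
    """
    target = np.array([a * np.cos(np.radians(angle_deg)),
                       b * np.sin(np.radians(angle_deg))])
    mids = (verts + np.roll(verts, -1, axis=0)) / 2.0
    return mids[np.argmin(np.linalg.norm(mids - target, axis=1))]


def _ellipse_outward_normal(point: np.ndarray, a: float, b: float) -> np.ndarray:
    n = np.array([point[0] / a**2, point[1] / b**2])
    return n / np.linalg.norm(n)


def build_geometry(spec: GeometrySpec, rng: Optional[np.random.Generator] = None) -> NeuronGeometry:
    """Realise a :class:`GeometrySpec` as a concrete :class:`NeuronGeometry`."""
    rng = rng if rng is not None else np.random.default_rng(0)
    a, b = spec.soma_axes
    verts = _ellipse_polygon(a, b, spec.n_boundary_vertices)
    axon_entry = _edge_midpoint_near(verts, a, b, spec.axon_angle_deg)
    dend_entries, branchpoints = {}, {}
    for i, ang in enumerate(spec.dendrite_angles_deg, start=1):
        name = f"dendrite_{i}"
        e = _edge_midpoint_near(verts, a, b, ang)
        dend_entries[name] = e
        branchpoints[name] = e + spec.dendrite_length * _ellipse_outward_normal(e, a, b)
    nucleus = None
    f = spec.nucleus_fraction
    if f > 0:
        nucleus = Polygon(_ellipse_polygon(f * a, f * b, spec.n_boundary_vertices))
    stacks = []
    entries = [axon_entry] + list(dend_entries.values())
    tries = 0
    while len(stacks) < spec.n_golgi and tries < 10000:
        tries += 1
        p = rng.uniform(-a, a), rng.uniform(-b, b)
        r2 = (p[0] / a) ** 2 + (p[1] / b) ** 2
        if not (r2 < 0.88**2):
            continue
        if f > 0 and (p[0] / (f * a)) ** 2 + (p[1] / (f * b)) ** 2 < 1.05**2:
            continue
        if any(np.linalg.norm(np.array(p) - e) < 2.2 for e in entries):
            continue
        if any(np.linalg.norm(np.array(p) - s.center) < 1.5 * spec.golgi_radius for s in stacks):
            continue
        stacks.append(GolgiStack(name=f"stack_{len(stacks):02d}", center=np.array(p),
                                 association_radius=spec.golgi_radius))
    if len(stacks) < spec.n_golgi:
        raise ValueError("geometry construction failed: could not place Golgi stacks")
    return NeuronGeometry(
        soma=Polygon(verts),
        nucleus=nucleus,
        axon_entry=axon_entry,
        dendrite_entries=dend_entries,
        dendrite_branchpoints=branchpoints,
        golgi_stacks=tuple(stacks),
        frame_interval=5.0,
    )


def _rotate(v: np.ndarray, deg: float) -> np.ndarray:
    r = np.radians(deg)
    c, s = np.cos(r), np.sin(r)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def _unit_toward(frm: np.ndarray, to: np.ndarray) -> np.ndarray:
    v = to - frm
    return v / np.linalg.norm(v)


def _segment_ellipse_exit(p: np.ndarray, q: np.ndarray, a: float, b: float) -> Optional[float]:
    """Parameter t in (0, 1] where segment p→q first crosses the ellipse, or None."""
    d = q - p
    A = (d[0] / a) ** 2 + (d[1] / b) ** 2
    B = 2 * (p[0] * d[0] / a**2 + p[1] * d[1] / b**2)
    C = (p[0] / a) ** 2 + (p[1] / b) ** 2 - 1.0
    disc = B * B - 4 * A * C
    if A == 0 or disc < 0:
        return None
    roots = sorted([(-B - np.sqrt(disc)) / (2 * A), (-B + np.sqrt(disc)) / (2 * A)])
    for t in roots:
        if 1e-12 < t <= 1.0:
            return float(t)
    return None


class _TruePath:
    """Exact polyline of one simulated comet plus its direction-change vertices."""

    def __init__(self, origin):
        self.pts = [np.asarray(origin, float)]
        self.guided_turns: list[int] = []  # vertex sample indices
        self.collisions: list[int] = []

    def append(self, p):
        self.pts.append(np.asarray(p, float))

    @property
    def xy(self) -> np.ndarray:
        return np.asarray(self.pts)


def _turn_label(
    path: _TruePath,
    geometry: NeuronGeometry,
    params: TurningParams,
) -> tuple[bool, bool, bool]:
    """(qualifies, turned, cortex_traveller) from the exact polyline.

    Applies the package's operational turning definition directly to the
    true vertex structure (segment directions between direction-change
    vertices; the sharpest intervening vertex must lie away from the cortex
    and nucleus), independent of the sampled-window detector.
    """
    import shapely

    xy = path.xy
    inside = shapely.intersects_xy(geometry.soma, xy[:, 0], xy[:, 1])
    stop = int(np.argmin(inside)) if not inside.all() else len(xy)
    if not inside[0] or stop < 2:
        return False, False, False
    xy = xy[:stop]
    m = len(xy)
    steps = np.diff(xy, axis=0)
    path_len = float(np.linalg.norm(steps, axis=1).sum())
    pts_geom = shapely.points(xy)
    d_cortex = shapely.distance(pts_geom, geometry.soma.exterior)
    cortex_traveller = bool(np.sum(d_cortex <= params.cortex_margin) >= 0.5 * m)
    qualifies = path_len > params.min_path_length and not cortex_traveller
    if not qualifies:
        return False, False, cortex_traveller
    d_nuc = (shapely.distance(pts_geom, geometry.nucleus.exterior)
             if geometry.nucleus is not None else np.full(m, np.inf))
    # exact-path form of the turning rule: pairwise over raw step directions
    # (every sampled point of the true path is a path vertex), the sharpest
    # intervening vertex must lie away from cortex and nucleus
    step_n = np.linalg.norm(steps, axis=1)
    nz = step_n > 1e-12
    unit = np.where(nz[:, None], steps / np.where(nz, step_n, 1.0)[:, None], 0.0)
    valid = nz[:-1] & nz[1:]
    cosv = np.einsum("ij,ij->i", steps[:-1], steps[1:]) / np.where(
        valid, step_n[:-1] * step_n[1:], 1.0)
    step_change = np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0)))
    step_change[~valid] = 0.0
    vertex_ok = (d_cortex > params.cortex_margin) & (d_nuc > params.cortex_margin)
    cos_thresh = np.cos(np.radians(params.turn_angle_threshold))
    cand = np.argwhere(np.triu(unit @ unit.T <= cos_thresh, k=1) & np.outer(nz, nz))
    for i, j in cand:
        ks = np.arange(i + 1, j + 1)
        ks = ks[(ks >= 1) & (ks <= m - 2)]
        if ks.size == 0:
            continue
        k = int(ks[np.argmax(step_change[ks - 1])])
        if vertex_ok[k]:
            return True, True, cortex_traveller
    return True, False, cortex_traveller


def simulate_neuron(
    config: SimulationConfig,
    turning_params: TurningParams = TurningParams(),
    movie_id: str = "sim",
) -> tuple[NeuronGeometry, list[CometTrack], list[GroundTruth]]:
    """Simulate one neuron's worth of comet tracks with ground truth.

    Fixed ``config.seed`` gives bit-identical output.  Gate outcomes in the
    ground truth are exact Bernoulli draws; turn/qualification labels are
    evaluated on the exact (noise-free) path.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    spec = config.geometry
    a, b = spec.soma_axes
    f = spec.nucleus_fraction
    geometry = build_geometry(spec, rng)
    zones = [build_entry_zone(geometry, n, width=config.zone_width,
                              caliber=config.zone_caliber)
             for n in geometry.neurite_names]
    zone_centers = np.array([z.center for z in zones])
    zone_reach = config.zone_caliber / 2.0 + config.zone_width
    dt = config.frame_interval
    step = config.growth_speed * dt
    p_cat = 1.0 - np.exp(-config.catastrophe_rate * dt)
    entries = [geometry.axon_entry] + [geometry.dendrite_entries[k]
                                       for k in sorted(geometry.dendrite_entries)]

    def draw_origin():
        if geometry.golgi_stacks and rng.random() < config.frac_golgi_origin:
            s = geometry.golgi_stacks[rng.integers(len(geometry.golgi_stacks))]
            r = 0.3 * s.association_radius * np.sqrt(rng.random())
            ang = rng.uniform(0, 2 * np.pi)
            return s.center + r * np.array([np.cos(ang), np.sin(ang)]), s.name
        while True:
            p = np.array([rng.uniform(-a, a), rng.uniform(-b, b)])
            if (p[0] / a) ** 2 + (p[1] / b) ** 2 >= 0.95**2:
                continue
            if f > 0 and (p[0] / (f * a)) ** 2 + (p[1] / (f * b)) ** 2 < 1.1**2:
                continue
            if min(np.linalg.norm(p - e) for e in entries) < 2.0:
                continue
            return p, None

    def vm(kappa):
        return rng.vonmises(0.0, kappa) if kappa > 0 else rng.uniform(-np.pi, np.pi)

    tracks, truths = [], []
    for ci in range(config.n_comets):
        origin, stack = draw_origin()
        theta = np.degrees(vm(config.kappa_nucleation)) if stack is not None \
            else np.degrees(rng.uniform(-np.pi, np.pi))
        direction = _rotate(_unit_toward(origin, geometry.axon_entry), theta)
        path = _TruePath(origin)
        pos = origin.copy()
        gate_contacted = gate_outcome = None
        cause = "max_frames"
        k = 0
        while k < config.max_frames:
            k += 1
            if k > 2 and rng.random() < p_cat:
                cause = "catastrophe"
                break
            if rng.random() < config.p_turn_per_frame:
                jitter = np.degrees(vm(config.turn_jitter_kappa))
                new_dir = _rotate(_unit_toward(pos, geometry.axon_entry), jitter)
                if np.linalg.norm(new_dir - direction) > 1e-9:
                    path.guided_turns.append(len(path.pts) - 1)
                    direction = new_dir
            q = pos + step * direction
            # --- entry-zone gate ---
            if gate_contacted is None:
                near = np.linalg.norm(zone_centers - q, axis=1) < zone_reach + step
                hit_zone = None
                if near.any():
                    seg = LineString([pos, q])
                    for zi in np.flatnonzero(near):
                        if zones[zi].band.intersects(seg):
                            hit_zone = zones[zi]
                            break
                if hit_zone is not None:
                    gate_contacted = hit_zone.neurite_name
                    p_enter = (config.p_enter_axon if hit_zone.kind == "axon"
                               else config.p_enter_dendrite)
                    chord = LineString([pos, q]).intersection(hit_zone.band)
                    mid = np.asarray(chord.interpolate(0.5, normalized=True).coords[0])
                    if rng.random() < p_enter:
                        gate_outcome = "entered"
                        cause = "entered"
                        _extend_through_gate(path, pos, mid, direction, hit_zone, step)
                    else:
                        gate_outcome = "rejected"
                        cause = "gate_rejected"
                        path.append(mid)
                    break
            # --- cortex / nuclear envelope reflection ---
            bounced = False
            t_exit = _segment_ellipse_exit(pos, q, a, b)
            if t_exit is not None:
                hit = pos + t_exit * (q - pos)
                n = _ellipse_outward_normal(hit, a, b)
                direction = direction - 2.0 * (direction @ n) * n
                q = hit - 1e-9 * n
                bounced = True
            elif f > 0:
                in_nuc = (q[0] / (f * a)) ** 2 + (q[1] / (f * b)) ** 2 < 1.0
                if in_nuc:
                    t_hit = _segment_ellipse_exit(pos, q, f * a, f * b)
                    if t_hit is not None:
                        hit = pos + t_hit * (q - pos)
                        n = _ellipse_outward_normal(hit, f * a, f * b)  # out of nucleus
                        direction = direction - 2.0 * (direction @ n) * n
                        q = hit + 1e-9 * n
                        bounced = True
            if bounced:
                path.collisions.append(len(path.pts))
            path.append(q)
            pos = q
        xy = path.xy
        if len(xy) < 3:  # pad a final straight step so every track is analysable
            path.append(xy[-1] + 0.25 * step * direction)
            xy = path.xy
        qualifies, turned, cortex = _turn_label(path, geometry, turning_params)
        noisy = _consistent_noise(xy, zones, gate_contacted, gate_outcome,
                                  rng, config.position_noise_sd)
        f0 = int(rng.integers(1, 21))
        t = (f0 + np.arange(len(xy))) * dt
        cid = f"{movie_id}_c{ci:04d}"
        tracks.append(CometTrack(
            comet_id=cid, movie_id=movie_id,
            points=np.column_stack([t, noisy]),
            present_at_first_frame=False, frame_interval=dt,
        ))
        truths.append(GroundTruth(
            comet_id=cid, origin_stack=stack, true_initial_angle=float(theta),
            turn_frames=tuple(path.guided_turns),
            gate_contacted=gate_contacted, gate_outcome=gate_outcome,
            termination_cause=cause, qualifies_for_turning=qualifies,
            turned=turned, cortex_traveller=cortex,
        ))
    return geometry, tracks, truths


def _gate_labels_hold(noisy: np.ndarray, zones, gate_contacted, gate_outcome) -> bool:
    """True when the emitted polyline still scores the recorded gate events."""
    line = LineString(noisy)
    for z in zones:
        touches = line.intersects(z.band)
        if z.neurite_name != gate_contacted:
            if touches:
                return False
        else:
            crosses = line.intersects(z.outer_gate_line)
            if gate_outcome == "entered" and not (touches and crosses):
                return False
            if gate_outcome == "rejected" and not (touches and not crosses):
                return False
    return True


def _consistent_noise(xy: np.ndarray, zones, gate_contacted, gate_outcome,
                      rng: np.random.Generator, sd: float, tries: int = 20) -> np.ndarray:
    """Add localisation jitter without altering the scored gate events.

    Noise is drawn conditional on the emitted track still carrying the
    comet's recorded approach/entry outcome (redraw on the rare conflict);
    a conflict surviving all redraws falls back to the noise-free path so
    ground truth and emitted track never disagree.
    """
    if sd <= 0:
        return xy
    for _ in range(tries):
        noisy = xy + rng.normal(0.0, sd, xy.shape)
        if _gate_labels_hold(noisy, zones, gate_contacted, gate_outcome):
            return noisy
    logger.info("noise redraw limit reached; emitting a noise-free track")
    return xy


def _extend_through_gate(path: _TruePath, pos: np.ndarray, band_mid: np.ndarray,
                         direction: np.ndarray, zone: EntryZone, step: float) -> None:
    """Continue an entering comet through the outer gate and ~1 μm beyond.

    The comet is routed through the midpoint of its band chord; if its
    heading would miss the finite outer gate it is funnelled toward the
    gate centre (guidance into the neurite mouth).
    """
    n = zone.outward_normal
    t_hat = np.array([-n[1], n[0]])
    outer_c = zone.outer_gate.mean(axis=0)
    half = np.linalg.norm(zone.outer_gate[1] - zone.outer_gate[0]) / 2.0
    funnel = True
    if direction @ n > 0.2:
        t_cross = ((outer_c - band_mid) @ n) / (direction @ n)
        lateral = abs((band_mid + t_cross * direction - outer_c) @ t_hat)
        funnel = lateral > 0.9 * half
    if funnel:
        direction = _unit_toward(band_mid, outer_c + 1e-9 * n)
    if not np.allclose(band_mid, pos):
        path.collisions.append(len(path.pts))
        path.append(band_mid)
    pos = band_mid
    t_end = ((outer_c - pos) @ n + 1.0) / (direction @ n)
    travelled = step
    while travelled < t_end:
        path.append(pos + travelled * direction)
        travelled += step
    path.append(pos + t_end * direction)


def fixture_counts(
    approach_entry_counts: dict[str, tuple[int, int]],
    n_total: int,
    geometry_spec: Optional[GeometrySpec] = None,
    seed: int = 0,
    turning_counts: Optional[tuple[int, int]] = None,
    polarity_counts: Optional[tuple[int, int]] = None,
    polarity_dendrite: str = "dendrite_1",
    movie_id: str = "fixture",
) -> tuple[NeuronGeometry, list[CometTrack]]:
    """Deterministic tracks whose classified counts equal a requested table.

    ``approach_entry_counts`` maps neurite name → (n_approach, n_enter).
    ``turning_counts`` = (n_qualifying, n_turned) adds mid-soma tracks that
    enter the turning denominator (approach/entry fixtures are built short
    so they never qualify, mirroring the separate published denominators).
    ``polarity_counts`` = (n_anterograde, n_retrograde) adds tracks inside
    the proximal dendrite segment.  Path shapes contain no randomness; the
    ``seed`` argument is accepted for interface symmetry only.
    """
    del seed  # deterministic by design
    if geometry_spec is None:
        geometry_spec = GeometrySpec(nucleus_fraction=0.0, n_golgi=0)
    geometry = build_geometry(geometry_spec)
    zones = {n: build_entry_zone(geometry, n) for n in geometry.neurite_names}
    for name in approach_entry_counts:
        if name not in zones:
            raise ValueError(f"unknown neurite {name!r} in approach_entry_counts")
    n_approach_total = sum(na for na, _ in approach_entry_counts.values())
    n_qual = turning_counts[0] if turning_counts else 0
    n_turn = turning_counts[1] if turning_counts else 0
    if n_turn > n_qual:
        raise ValueError("turned count exceeds qualifying count")
    n_filler = n_total - n_approach_total - n_qual
    if n_filler < 0:
        raise ValueError("infeasible table: approach + turning counts exceed n_total")
    dt = 5.0
    tracks: list[CometTrack] = []

    def add(name: str, xy: np.ndarray):
        t = (1 + np.arange(len(xy))) * dt
        tracks.append(CometTrack(comet_id=name, movie_id=movie_id,
                                 points=np.column_stack([t, xy]),
                                 present_at_first_frame=False, frame_interval=dt))

    for name, (n_app, n_ent) in approach_entry_counts.items():
        if n_ent > n_app:
            raise ValueError(f"{name}: entries exceed approaches")
        z = zones[name]
        n = z.outward_normal
        t_hat = np.array([-n[1], n[0]])
        entry = geometry.entry_point(name)
        for i in range(n_app):
            off = ((i % 7) - 3) * 0.15 * t_hat
            if i < n_ent:  # crosses the outer gate into the neurite
                s_vals = np.arange(-1.8, 1.45, 0.4)
            else:  # terminates inside the band
                s_vals = np.append(np.arange(-1.8, -0.3, 0.35), -0.05)
            xy = entry + np.outer(s_vals, n) + off
            add(f"{movie_id}_{name}_app{i:04d}", xy)

    c0 = np.zeros(2)
    if turning_counts:
        for i in range(n_qual):
            phi = 2.399963 * i  # golden-angle spread
            vertex = c0 + 1.5 * np.array([np.cos(phi), np.sin(phi)])
            u = np.array([-np.sin(phi), np.cos(phi)])
            if i < n_turn:  # 90 degree vertex mid-soma
                v = np.array([-u[1], u[0]])
                legs = [vertex - (1.6 - 0.4 * j) * u for j in range(4)]
                legs += [vertex] + [vertex + 0.4 * (j + 1) * v for j in range(4)]
                xy = np.asarray(legs)
            else:  # straight > 2 μm chord, away from cortex and zones
                s_vals = np.arange(8) * 0.45
                xy = vertex - 1.6 * u + np.outer(s_vals, u)
            add(f"{movie_id}_turn{i:04d}", xy)

    for i in range(n_filler):
        phi = 2.399963 * (i + 0.5)
        p0 = c0 + 1.2 * np.array([np.cos(phi), np.sin(phi)])
        u = np.array([-np.sin(phi), np.cos(phi)])
        xy = np.asarray([p0, p0 + 0.25 * u, p0 + 0.5 * u])
        add(f"{movie_id}_fill{i:04d}", xy)

    if polarity_counts:
        n_ant, n_ret = polarity_counts
        entry = geometry.entry_point(polarity_dendrite)
        from .event_classification import dendrite_axis
        e0, u, _ = dendrite_axis(geometry, polarity_dendrite)
        t_hat = np.array([-u[1], u[0]])
        for i in range(n_ant + n_ret):
            off = ((i % 5) - 2) * 0.12 * t_hat
            s_vals = 0.5 + 0.4 * np.arange(5)
            if i >= n_ant:
                s_vals = s_vals[::-1]
            xy = e0 + np.outer(s_vals, u) + off
            add(f"{movie_id}_pol{i:04d}", xy)

    return geometry, tracks
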