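"""End-to-end orchestration: tracks → angles → resultants → events → report.

A run takes one or more named conditions (each a set of neurons, either
loaded from track/geometry files or simulated), measures initial growth
angles of Golgi-origin comets, builds per-stack resultant vectors and the
Monte-Carlo uniform null, classifies approach/entry/turning/polarity
events, summarises every quantity as a proportion with a Wilson 95% CI,
and compares conditions pairwise with chi-squared tests.  All tables are
written as delimited text next to a machine-readable manifest recording
every parameter and seed, so a run is reproducible from its bundle alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from shapely.geometry import Point

from . import __version__, circular_stats, inference_stats, track_io
from .event_classification import (
    CometEvents,
    TurningParams,
    classify_approach_entry,
    classify_dendrite_polarity,
    detect_turning,
    origin_in_zone,
    tabulate_events,
)
from .geometry import build_entry_zone, initial_growth_angle
from .synthetic_data import SimulationConfig, simulate_neuron
from .track_io import CometTrack, NeuronGeometry

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrackInputs:
    """One condition loaded from files: (track table, geometry) path pairs."""

    pairs: tuple[tuple[str, str], ...]
    dialect: str = "native"
    pixel_size: float = 0.1
    frame_interval: float = 5.0
    y_axis: str = "math"


@dataclass(frozen=True)
class SimInputs:
    """One condition produced by the simulator: n_neurons independent somas."""

    config: SimulationConfig
    n_neurons: int = 1


@dataclass(frozen=True)
class RunConfig:
    conditions: dict[str, Union[TrackInputs, SimInputs]]
    n_direction_points: int = 3
    zone_width: float = 0.5
    zone_caliber: float = 2.0
    turning: TurningParams = field(default_factory=TurningParams)
    angle_bin_width: float = 15.0  # degrees, folded-angle histogram
    length_bins: int = 10
    null_replicates: int = 3
    seed: int = 0
    outdir: Optional[str] = None


@dataclass
class ConditionReport:
    name: str
    n_tracks: int
    angles: pd.DataFrame
    angle_histogram: Optional[pd.DataFrame]
    angle_uniformity: Optional[inference_stats.ChiSquaredResult]
    resultants: pd.DataFrame
    upper_quadrant: Optional[inference_stats.ProportionResult]
    upper_quadrant_binomial_p: Optional[float]
    length_histogram: Optional[pd.DataFrame]
    length_chisq: Optional[inference_stats.ChiSquaredResult]
    events: list[CometEvents]
    summary: pd.DataFrame


@dataclass
class ReportBundle:
    conditions: dict[str, ConditionReport]
    comparisons: pd.DataFrame
    manifest: dict


def _load_condition(name: str, inputs) -> list[tuple[NeuronGeometry, list[CometTrack]]]:
    neurons = []
    if isinstance(inputs, SimInputs):
        for i in range(inputs.n_neurons):
            cfg = SimulationConfig(**{**asdict(inputs.config),
                                      "geometry": inputs.config.geometry,
                                      "seed": inputs.config.seed + i})
            geom, tracks, _ = simulate_neuron(cfg, movie_id=f"{name}_n{i:02d}")
            neurons.append((geom, tracks))
    elif isinstance(inputs, TrackInputs):
        for tracks_path, geom_path in inputs.pairs:
            geom = track_io.read_geometry(geom_path)
            tracks = track_io.read_tracks(
                tracks_path, dialect=inputs.dialect,
                frame_interval=inputs.frame_interval,
                pixel_size=inputs.pixel_size, y_axis=inputs.y_axis,
            )
            neurons.append((geom, tracks))
    else:
        raise TypeError(f"condition {name!r}: unsupported input type {type(inputs)}")
    return neurons


def classify_neuron(
    geometry: NeuronGeometry,
    tracks: list[CometTrack],
    config: RunConfig,
) -> list[CometEvents]:
    """Classify every track of one neuron into a :class:`CometEvents` record."""
    zones = [build_entry_zone(geometry, n, width=config.zone_width,
                              caliber=config.zone_caliber)
             for n in geometry.neurite_names]
    events = []
    for tr in tracks:
        in_soma = geometry.soma.covers(Point(tr.xy[0]))
        polarity = None
        dendrite_for_polarity = None
        if in_soma:
            excluded = origin_in_zone(tr, zones) is not None
            approached = entered = None
            approached_all = ()
            qualifies = turned = cortex = False
            if not excluded:
                ae = classify_approach_entry(tr, zones, geometry)
                approached, entered, approached_all = ae
                qualifies, turned, cortex = detect_turning(tr, geometry, config.turning)
                if entered is not None and entered != "axon":
                    dendrite_for_polarity = entered
            region = "soma"
        else:
            excluded = False
            approached = entered = None
            approached_all = ()
            qualifies = turned = cortex = False
            region = "other"
            for dname in sorted(geometry.dendrite_entries):
                try:
                    polarity = classify_dendrite_polarity(
                        tr, geometry, dname, zone_width=config.zone_width)
                    region = "proximal_dendrite"
                    break
                except ValueError:
                    continue
        if dendrite_for_polarity is not None:
            try:
                polarity = classify_dendrite_polarity(
                    tr, geometry, dendrite_for_polarity, zone_width=config.zone_width)
            except ValueError:
                polarity = None
        events.append(CometEvents(
            comet_id=tr.comet_id, origin_region=region,
            approached=approached, approached_all=approached_all, entered=entered,
            qualifies_for_turning=qualifies, turned=turned, cortex_traveller=cortex,
            dendrite_polarity=polarity, excluded_origin_in_zone=excluded,
        ))
    return events


def _analyse_condition(name: str, neurons, config: RunConfig,
                       null_seed: int) -> ConditionReport:
    angle_rows = []
    stack_angles: dict[tuple[int, str], list[float]] = {}
    events: list[CometEvents] = []
    n_tracks = 0
    for ni, (geom, tracks) in enumerate(neurons):
        tracks = track_io.filter_first_frame(tracks)
        n_tracks += len(tracks)
        for tr in tracks:
            if len(tr.points) < config.n_direction_points:
                continue
            try:
                ga = initial_growth_angle(tr, geom, config.n_direction_points)
            except ValueError:
                continue
            angle_rows.append({
                "neuron": ni, "comet_id": ga.comet_id,
                "theta_signed": ga.theta_signed, "theta_folded": ga.theta_folded,
                "origin_stack": ga.origin_stack or "",
            })
            if ga.origin_stack:
                stack_angles.setdefault((ni, ga.origin_stack), []).append(ga.theta_signed)
        events.extend(classify_neuron(geom, tracks, config))
    angles = pd.DataFrame(
        angle_rows, columns=["neuron", "comet_id", "theta_signed",
                             "theta_folded", "origin_stack"])

    # folded-angle frequency distribution of Golgi-origin comets vs uniform
    golgi_folded = angles.loc[angles["origin_stack"] != "", "theta_folded"].to_numpy()
    angle_hist = angle_uniformity = None
    if golgi_folded.size:
        edges = np.arange(0.0, 180.0 + config.angle_bin_width / 2, config.angle_bin_width)
        counts, _ = np.histogram(np.clip(golgi_folded, 0, 180 - 1e-9), bins=edges)
        angle_hist = pd.DataFrame({"bin_low": edges[:-1], "bin_high": edges[1:],
                                   "count": counts})
        if counts.sum() >= len(counts):
            angle_uniformity = inference_stats.chisq_gof(
                counts, np.full(len(counts), 1.0 / len(counts)))

    resultants = [circular_stats.stack_resultant(f"n{ni}_{sid}", a)
                  for (ni, sid), a in sorted(stack_angles.items()) if len(a) >= 2]
    upper = binom_p = None
    length_hist = length_chisq = None
    if resultants:
        upper = circular_stats.upper_quadrant_fraction(resultants)
        binom_p = inference_stats.binomial_upper_tail(upper.k, upper.n, 0.5)
        null = circular_stats.random_null(
            [r.n_comets for r in resultants], config.null_replicates, null_seed)
        try:
            length_hist, length_chisq = circular_stats.compare_length_distributions(
                [r.length_d for r in resultants], null,
                bins=np.linspace(0.0, 1.0, config.length_bins + 1))
        except ValueError as exc:
            logger.warning("condition %s: length-distribution test skipped (%s)", name, exc)

    return ConditionReport(
        name=name, n_tracks=n_tracks, angles=angles,
        angle_histogram=angle_hist, angle_uniformity=angle_uniformity,
        resultants=circular_stats.resultants_to_frame(resultants),
        upper_quadrant=upper, upper_quadrant_binomial_p=binom_p,
        length_histogram=length_hist, length_chisq=length_chisq,
        events=events, summary=tabulate_events(events),
    )


def _pairwise_comparisons(reports: dict[str, ConditionReport]) -> pd.DataFrame:
    rows = []
    names = list(reports)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            sa, sb = reports[a].summary, reports[b].summary
            for metric in sa["metric"]:
                ra = sa.loc[sa["metric"] == metric].iloc[0]
                rb = sb.loc[sb["metric"] == metric].iloc[0]
                if not (ra["defined"] and rb["defined"]):
                    continue
                res = inference_stats.compare_proportions(
                    int(ra["k"]), int(ra["n"]), int(rb["k"]), int(rb["n"]))
                rows.append({
                    "condition_a": a, "condition_b": b, "metric": metric,
                    "k_a": int(ra["k"]), "n_a": int(ra["n"]),
                    "k_b": int(rb["k"]), "n_b": int(rb["n"]),
                    "statistic": res.statistic, "p_value": res.p_value,
                })
    return pd.DataFrame(rows, columns=["condition_a", "condition_b", "metric",
                                       "k_a", "n_a", "k_b", "n_b",
                                       "statistic", "p_value"])


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run the full analysis for every condition and assemble the report bundle."""
    reports: dict[str, ConditionReport] = {}
    for ci, (name, inputs) in enumerate(config.conditions.items()):
        neurons = _load_condition(name, inputs)
        reports[name] = _analyse_condition(name, neurons, config,
                                           null_seed=config.seed + 1000 * (ci + 1))
    comparisons = _pairwise_comparisons(reports)
    manifest = {
        "software": {"name": "cometpol", "version": __version__},
        "seed": config.seed,
        "parameters": {
            "n_direction_points": config.n_direction_points,
            "zone_width_um": config.zone_width,
            "zone_caliber_um": config.zone_caliber,
            "turning": asdict(config.turning),
            "angle_bin_width_deg": config.angle_bin_width,
            "length_bins": config.length_bins,
            "null_replicates": config.null_replicates,
            "ci_method": "wilson",
            "two_sample_test": "pearson_chi2_nocorrection",
        },
        "conditions": {
            name: (asdict(inp) if isinstance(inp, (TrackInputs, SimInputs)) else str(inp))
            for name, inp in config.conditions.items()
        },
    }
    bundle = ReportBundle(conditions=reports, comparisons=comparisons, manifest=manifest)
    if config.outdir is not None:
        write_bundle(bundle, config.outdir)
    return bundle


def write_bundle(bundle: ReportBundle, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, rep in bundle.conditions.items():
        rep.angles.to_csv(out / f"angles_{name}.csv", index=False)
        rep.resultants.to_csv(out / f"resultants_{name}.csv", index=False)
        rep.summary.to_csv(out / f"summary_{name}.csv", index=False)
        if rep.angle_histogram is not None:
            rep.angle_histogram.to_csv(out / f"angle_histogram_{name}.csv", index=False)
        if rep.length_histogram is not None:
            rep.length_histogram.to_csv(out / f"length_histogram_{name}.csv", index=False)
        extra = {
            "n_tracks": rep.n_tracks,
            "angle_uniformity": asdict(rep.angle_uniformity) if rep.angle_uniformity else None,
            "upper_quadrant": asdict(rep.upper_quadrant) if rep.upper_quadrant else None,
            "upper_quadrant_binomial_p": rep.upper_quadrant_binomial_p,
            "length_chisq": asdict(rep.length_chisq) if rep.length_chisq else None,
        }
        (out / f"stats_{name}.json").write_text(json.dumps(extra, indent=2))
    bundle.comparisons.to_csv(out / "comparisons.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2, default=str))
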