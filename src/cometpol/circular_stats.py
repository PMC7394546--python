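"""Per-Golgi-stack resultant vectors and the Monte-Carlo uniform-angle null.

Each comet's signed initial angle θ becomes a unit vector (sin θ, cos θ):
the cosine is deliberately the Y component, so that the positive Y axis is
the toward-axon direction and the upper quadrants of the resultant scatter
mean "average growth toward the axon".  For each Golgi stack that produced
two or more comets, the unit vectors are averaged into a normalised
resultant whose length d ∈ [0, 1] measures how similar the comet angles
were (d = 1: identical; d = 0: perfectly cancelling).

The null model replaces every comet angle with an independent draw from
Uniform(−180, 180), preserving the per-stack comet counts, and recomputes
the resultant lengths; comparing the observed length distribution against
this null asks whether comets from the same stack emerge more similarly
oriented than chance would allow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import inference_stats
from .inference_stats import ChiSquaredResult, ProportionResult

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StackResultant:
    stack_id: str
    n_comets: int
    resultant_x: float
    resultant_y: float
    length_d: float
    mean_angle: float  # degrees from the toward-axon (+Y) axis, CCW positive

    def __post_init__(self):
        if self.n_comets < 2:
            raise ValueError("stack resultants are defined for stacks with >=2 comets")
        d = float(np.hypot(self.resultant_x, self.resultant_y))
        if abs(d - self.length_d) > 1e-12:
            raise ValueError("length_d inconsistent with resultant components")
        if not (0.0 <= self.length_d <= 1.0 + 1e-12):
            raise ValueError("length_d outside [0, 1]")


@dataclass(frozen=True)
class NullDistribution:
    """Resultant lengths under the uniform-angle null, one array per replicate set."""

    replicate_lengths: tuple[np.ndarray, ...]
    comet_counts: tuple[int, ...]
    n_replicates: int
    seed: int

    def pooled(self) -> np.ndarray:
        return np.concatenate(self.replicate_lengths)


def comet_unit_vector(theta_signed: float) -> tuple[float, float]:
    """Unit vector (sin θ, cos θ) for a signed angle in (−180, 180].

    cos θ is the Y (toward-axon) component; sin θ is X.
    """
    if not (-180.0 < theta_signed <= 180.0 + 1e-12):
        raise ValueError(f"theta_signed {theta_signed} out of (-180, 180]")
    r = np.radians(theta_signed)
    return float(np.sin(r)), float(np.cos(r))


def stack_resultant(stack_id: str, angles) -> StackResultant:
    """Normalised resultant vector of one stack's comet angles.

    Unit vectors are summed and divided by the comet count, so the maximum
    possible length is 1 irrespective of how many comets the stack produced.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size < 2:
        raise ValueError(f"stack {stack_id}: needs >=2 comet angles, got {angles.size}")
    if np.any(angles <= -180.0 - 1e-12) or np.any(angles > 180.0 + 1e-12):
        raise ValueError(f"stack {stack_id}: angles out of (-180, 180]")
    r = np.radians(angles)
    x = float(np.sin(r).mean())
    y = float(np.cos(r).mean())
    d = float(np.hypot(x, y))
    return StackResultant(
        stack_id=str(stack_id),
        n_comets=int(angles.size),
        resultant_x=x,
        resultant_y=y,
        length_d=min(d, 1.0),
        mean_angle=float(np.degrees(np.arctan2(x, y))),
    )


def resultants_to_frame(resultants) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.stack_id, r.n_comets, r.resultant_x, r.resultant_y, r.length_d, r.mean_angle)
         for r in resultants],
        columns=["stack_id", "n_comets", "x", "y", "d", "mean_angle"],
    )


def upper_quadrant_fraction(resultants) -> ProportionResult:
    """Fraction of stack resultants pointing toward the axon (resultant_y > 0).

    Resultants with y exactly 0 count as neither quadrant and are dropped
    from the denominator.
    """
    resultants = list(resultants)
    if not resultants:
        raise ValueError("no stack resultants supplied")
    ys = np.array([r.resultant_y for r in resultants])
    on_axis = int(np.sum(ys == 0.0))
    if on_axis:
        logger.info("upper_quadrant_fraction: %d resultant(s) on the x-axis excluded", on_axis)
    n = ys.size - on_axis
    k = int(np.sum(ys > 0.0))
    return inference_stats.proportion(k, n)


def random_null(comet_counts, n_replicates: int, seed: int) -> NullDistribution:
    """Resultant lengths for stacks of uniform-random comet angles.

    Each replicate redraws every comet angle from continuous
    Uniform(−180, 180), keeping the per-stack comet counts.  Replicates use
    independent substreams spawned from ``seed``, so a fixed seed gives
    bit-identical output.
    """
    counts = tuple(int(c) for c in comet_counts)
    if any(c < 2 for c in counts):
        raise ValueError("all comet counts must be >= 2")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(n_replicates)
    reps = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        lengths = np.empty(len(counts))
        for i, c in enumerate(counts):
            r = np.radians(rng.uniform(-180.0, 180.0, size=c))
            lengths[i] = np.hypot(np.sin(r).mean(), np.cos(r).mean())
        reps.append(lengths)
    return NullDistribution(
        replicate_lengths=tuple(reps),
        comet_counts=counts,
        n_replicates=int(n_replicates),
        seed=int(seed),
    )


def compare_length_distributions(
    observed,
    null: NullDistribution,
    bins=None,
) -> tuple[pd.DataFrame, ChiSquaredResult]:
    """Histogram observed resultant lengths against the pooled null.

    Returns a per-bin frequency table and a one-way chi-squared of the
    observed counts against the null-derived expected proportions.  Bins
    whose pooled-null mass is zero are merged downward before the test so
    every expected count is positive.
    """
    observed = np.asarray(list(observed), dtype=float)
    if observed.size == 0:
        raise ValueError("no observed resultant lengths")
    if bins is None:
        bins = np.linspace(0.0, 1.0, 11)
    bins = np.asarray(bins, dtype=float)
    if bins[0] > 1e-12 or bins[-1] < 1.0 - 1e-12:
        raise ValueError("bins must cover [0, 1]")
    obs_counts, _ = np.histogram(observed, bins=bins)
    null_counts, _ = np.histogram(null.pooled(), bins=bins)
    table = pd.DataFrame({
        "bin_low": bins[:-1],
        "bin_high": bins[1:],
        "observed": obs_counts,
        "observed_freq": obs_counts / obs_counts.sum(),
        "null": null_counts,
        "null_freq": null_counts / null_counts.sum(),
    })
    # merge zero-mass null bins into their lower neighbour for the test
    o, e = [], []
    for oc, nc in zip(obs_counts, null_counts):
        if e and nc == 0:
            o[-1] += oc
            e[-1] += nc
        else:
            o.append(int(oc))
            e.append(int(nc))
    while len(e) > 1 and e[0] == 0:  # leading zero-mass bins merge upward
        o[1] += o[0]
        e[1] += e[0]
        o, e = o[1:], e[1:]
    if len(e) < 2:
        raise ValueError("null distribution concentrated in a single bin; cannot test")
    props = np.asarray(e, dtype=float) / sum(e)
    result = inference_stats.chisq_gof(o, props)
    return table, result
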