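"""Proportion and frequency inference used throughout the pipeline.

Every bar-chart quantity is a proportion k/n reported as a percentage with
a Wilson score 95% confidence interval.  Frequency distributions are tested
against chance expectations with one-way Pearson chi-squared
goodness-of-fit tests; pairs of proportions (e.g. control vs RNAi) are
compared with a 2x2 Pearson chi-squared without continuity correction; and
the skew of resultant vectors between upper and lower quadrants is
assessed with an exact binomial upper-tail probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProportionResult:
    """k of n as a percentage with a 95% Wilson score interval (percent units)."""

    k: int
    n: int
    percent: float
    ci_low: float
    ci_high: float
    method: str = "wilson"

    def __post_init__(self):
        if not (0 <= self.k <= self.n):
            raise ValueError(f"k={self.k} not in [0, n={self.n}]")
        if not (self.ci_low - 1e-9 <= self.percent <= self.ci_high + 1e-9):
            raise ValueError("confidence interval does not bracket the estimate")

    def __str__(self):  # display precision matches the reporting convention
        return f"{self.k}/{self.n} = {self.percent:.1f}% (95% CI {self.ci_low:.1f}-{self.ci_high:.1f})"


@dataclass(frozen=True)
class ChiSquaredResult:
    statistic: float
    df: int
    p_value: float
    method: str = "pearson_chi2"

    def __post_init__(self):
        if self.statistic < 0 or not (0.0 <= self.p_value <= 1.0):
            raise ValueError("invalid chi-squared result")


def proportion(k: int, n: int) -> ProportionResult:
    """Proportion with Wilson score 95% CI, on the percent scale."""
    if n < 1:
        raise ValueError("proportion undefined for n = 0")
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return ProportionResult(
        k=int(k), n=int(n),
        percent=100.0 * k / n,
        ci_low=100.0 * float(lo),
        ci_high=100.0 * float(hi),
    )


def chisq_gof(observed, expected_proportions) -> ChiSquaredResult:
    """One-way chi-squared goodness-of-fit of counts against expected proportions."""
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(expected_proportions, dtype=float)
    if obs.shape != props.shape:
        raise ValueError("observed and expected_proportions must have equal length")
    if np.any(obs < 0):
        raise ValueError("negative observed count")
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError(f"expected proportions sum to {props.sum():.12g}, not 1")
    expected = obs.sum() * props
    if np.any(expected <= 0):
        raise ValueError("zero expected count; merge bins before testing")
    stat, p = stats.chisquare(obs, f_exp=expected)
    return ChiSquaredResult(
        statistic=float(stat), df=obs.size - 1, p_value=float(p),
        method="pearson_chi2_gof",
    )


def compare_proportions(k1: int, n1: int, k2: int, n2: int) -> ChiSquaredResult:
    """2x2 Pearson chi-squared (no continuity correction) for two proportions."""
    if n1 < 1 or n2 < 1:
        raise ValueError("both sample sizes must be >= 1")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if np.any(table < 0):
        raise ValueError("counts exceed sample sizes")
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        logger.info("compare_proportions: degenerate margins (all successes or all "
                    "failures); p = 1 by convention")
        return ChiSquaredResult(statistic=0.0, df=1, p_value=1.0,
                                method="pearson_chi2_nocorrection")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return ChiSquaredResult(statistic=float(stat), df=1, p_value=float(p),
                            method="pearson_chi2_nocorrection")


def binomial_upper_tail(k: int, n: int, p0: float) -> float:
    """Exact P(X >= k) for X ~ Binomial(n, p0)."""
    if not (0 <= k <= n):
        raise ValueError(f"k={k} not in [0, n={n}]")
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must be in (0, 1)")
    return float(stats.binom.sf(k - 1, n, p0))


def format_p(p: float) -> str:
    """Display convention: two significant figures, thresholded at p<0.001."""
    if p < 0.001:
        return "p<0.001"
    return f"p={p:.2g}"
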