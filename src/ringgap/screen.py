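"""Six-category primary-screen classification of fly lines.

Each line is summarised by the median, over its replicate experiments, of
two parameters: the maximum mean distance from centre (x, relative units)
and the percentage of drowned flies (y). Population boundaries are the 10th
and 90th percentiles of the line x-medians and the 90th percentile of the
line y-medians; under-/over-performers on x and high-death lines on y are
flagged relative to those boundaries and combined into six categories:

    x <= x_low,  y >= y_high  -> very_clumsy  (drown already at small gaps)
    x <= x_low                -> overcautious (barely leave the recess)
    x >= x_high, y >= y_high  -> overeager    (far out, at high cost)
    x >= x_high               -> super_climber
    y >= y_high               -> clumsy       (normal reach, many losses)
    otherwise                 -> normal

Comparisons are inclusive so all lines tied at a boundary of the discrete
death statistic (multiples of 100/15 %) are flagged; there is no low-death
category. Quantiles use linear interpolation of order statistics throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
import warnings

import numpy as np

from .ring_analysis import RingAssayMetrics
from .simulate import ValidationError


class Category(str, Enum):
    NORMAL = "normal"
    OVERCAUTIOUS = "overcautious"
    VERY_CLUMSY = "very_clumsy"
    CLUMSY = "clumsy"
    OVEREAGER = "overeager"
    SUPER_CLIMBER = "super_climber"


@dataclass(frozen=True)
class LineSummary:
    """Per-line median screen statistics over replicates."""

    line_id: str
    n_replicates: int
    median_max_mean_distance: float   # x
    median_pct_dead: float            # y


@dataclass(frozen=True)
class PopulationBoundaries:
    """Quantile boundaries over the screened lines' medians."""

    x_low: float    # 10th percentile of x-medians
    x_high: float   # 90th percentile of x-medians
    y_high: float   # 90th percentile of y-medians


@dataclass(frozen=True)
class ControlSummary:
    """Median/quartile/decile cross of the pooled control experiments."""

    x_median: float
    x_q25: float
    x_q75: float
    x_q10: float
    x_q90: float
    y_median: float
    y_q25: float
    y_q75: float
    y_q10: float
    y_q90: float
    n: int


def summarize_line(metrics: list[RingAssayMetrics]) -> LineSummary:
    """Median max-mean-distance and percent-dead across replicates."""
    if not metrics:
        raise ValidationError("cannot summarise a line without replicates")
    if len(metrics) < 3:
        warnings.warn(
            f"line {metrics[0].line_id!r}: only {len(metrics)} replicate(s); "
            "the screen used at least 3",
            stacklevel=2,
        )
    return LineSummary(
        line_id=metrics[0].line_id,
        n_replicates=len(metrics),
        median_max_mean_distance=float(np.median([m.max_mean_distance for m in metrics])),
        median_pct_dead=float(np.median([m.pct_dead for m in metrics])),
    )


def compute_boundaries(summaries: list[LineSummary]) -> PopulationBoundaries:
    """Empirical 10th/90th percentile boundaries over the line medians."""
    if len(summaries) < 10:
        raise ValidationError("need at least 10 lines to place decile boundaries")
    x = np.array([s.median_max_mean_distance for s in summaries])
    y = np.array([s.median_pct_dead for s in summaries])
    return PopulationBoundaries(
        x_low=float(np.percentile(x, 10)),
        x_high=float(np.percentile(x, 90)),
        y_high=float(np.percentile(y, 90)),
    )


def classify_line(summary: LineSummary, boundaries: PopulationBoundaries) -> Category:
    """Assign exactly one of the six screen categories."""
    x = summary.median_max_mean_distance
    y = summary.median_pct_dead
    high_death = y >= boundaries.y_high
    if x <= boundaries.x_low:
        return Category.VERY_CLUMSY if high_death else Category.OVERCAUTIOUS
    if x >= boundaries.x_high:
        return Category.OVEREAGER if high_death else Category.SUPER_CLIMBER
    return Category.CLUMSY if high_death else Category.NORMAL


def category_census(categories: list[Category]) -> dict[Category, float]:
    """Percentage of lines per category (sums to 100 up to rounding)."""
    if not categories:
        raise ValidationError("empty category list")
    n = len(categories)
    return {c: 100.0 * sum(1 for k in categories if k == c) / n for c in Category}


def control_summary(metrics: list[RingAssayMetrics]) -> ControlSummary:
    """Summary cross of the pooled control experiments (same quantile rule)."""
    if len(metrics) < 2:
        raise ValidationError("need at least 2 control experiments")
    x = np.array([m.max_mean_distance for m in metrics])
    y = np.array([m.pct_dead for m in metrics])
    qx = np.percentile(x, [10, 25, 50, 75, 90])
    qy = np.percentile(y, [10, 25, 50, 75, 90])
    return ControlSummary(
        x_q10=float(qx[0]), x_q25=float(qx[1]), x_median=float(qx[2]),
        x_q75=float(qx[3]), x_q90=float(qx[4]),
        y_q10=float(qy[0]), y_q25=float(qy[1]), y_median=float(qy[2]),
        y_q75=float(qy[3]), y_q90=float(qy[4]),
        n=len(metrics),
    )
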