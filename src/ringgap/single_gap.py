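"""Per-fly single-gap climbing statistics and rank-sum comparisons.

Each fly contributes 10 voluntary approaches at one gap width. The per-fly
fractions (attempts, falls, crossings per approach; falls per attempt) are
summarised as box statistics (median, quartiles, deciles) per line × width
and compared against the control line with a two-sided Wilcoxon rank-sum
test per gap width, uncorrected across widths, with the usual star coding
(* p<0.05, ** p<0.01, *** p<0.001).

The rank-sum test uses exact enumeration of all group-label assignments
when the pooled sample size is at most 20 (midranks for ties), and the
tie- and continuity-corrected normal approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import combinations
import warnings

import numpy as np
from scipy import stats

from .simulate import ApproachLog, ValidationError

EXACT_MAX_POOLED_N = 20


@dataclass(frozen=True)
class FlyGapStats:
    """One fly's outcome fractions over its 10 approaches."""

    fly_id: int
    n_approaches: int
    frac_attempt: float
    frac_fall: float            # falls per approach
    frac_cross: float
    frac_fall_given_attempt: float

    def __post_init__(self) -> None:
        if self.frac_cross > self.frac_attempt + 1e-12:
            raise ValidationError("frac_cross cannot exceed frac_attempt")
        if self.frac_fall > self.frac_attempt + 1e-12:
            raise ValidationError("frac_fall cannot exceed frac_attempt")


@dataclass(frozen=True)
class BoxStats:
    median: float
    q25: float
    q75: float
    q10: float
    q90: float
    n: int


class Stars(str, Enum):
    NS = "ns"
    ONE = "*"
    TWO = "**"
    THREE = "***"


@dataclass(frozen=True)
class GroupComparison:
    gap_width: float
    metric: str
    statistic: float   # rank sum of the test group
    p_value: float
    stars: Stars


def per_fly_fractions(log: ApproachLog, n_approaches: int = 10) -> list[FlyGapStats]:
    """Counts/10 fractions per fly; every fly must have exactly 10 events.

    ``frac_fall`` is per approach; ``frac_fall_given_attempt`` is the
    falls-among-attempts reading (0 for a fly without attempts).
    """
    log.validate(n_approaches)
    out = []
    for fly_id, events in sorted(log.by_fly().items()):
        n_att = sum(ev.attempted for ev in events)
        n_fall = sum(ev.fell for ev in events)
        n_cross = sum(ev.crossed for ev in events)
        out.append(
            FlyGapStats(
                fly_id=fly_id,
                n_approaches=n_approaches,
                frac_attempt=n_att / n_approaches,
                frac_fall=n_fall / n_approaches,
                frac_cross=n_cross / n_approaches,
                frac_fall_given_attempt=n_fall / n_att if n_att else 0.0,
            )
        )
    return out


def box_stats(values) -> BoxStats:
    """Median, 25/75 quartiles and 10/90 deciles by linear interpolation."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("box_stats needs at least one value")
    q10, q25, med, q75, q90 = np.percentile(values, [10, 25, 50, 75, 90])
    return BoxStats(median=float(med), q25=float(q25), q75=float(q75),
                    q10=float(q10), q90=float(q90), n=values.size)


def _exact_rank_sum_p(ranks: np.ndarray, n_a: int, w_obs: float) -> float:
    """Two-sided p over all C(n, n_a) assignments of group-A labels."""
    n = len(ranks)
    idx = np.array(list(combinations(range(n), n_a)), dtype=np.intp)
    sums = ranks[idx].sum(axis=1)
    tol = 1e-9
    p_le = np.mean(sums <= w_obs + tol)
    p_ge = np.mean(sums >= w_obs - tol)
    return min(1.0, 2.0 * min(p_le, p_ge))


def rank_sum_test(group_a, group_b, method: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test: ``(rank sum of group_a, p)``.

    ``method="auto"`` uses exact enumeration (midranks for ties) when the
    pooled size is <= 20 and otherwise the normal approximation with tie
    and continuity correction; ``"exact"`` and ``"asymptotic"`` force
    either path.
    """
    if method not in ("auto", "exact", "asymptotic"):
        raise ValidationError(f"unknown method {method!r}")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)   # midranks
    w_a = float(ranks[: a.size].sum())
    if np.all(pooled == pooled[0]):
        return w_a, 1.0
    if method == "exact" or (method == "auto" and pooled.size <= EXACT_MAX_POOLED_N):
        return w_a, _exact_rank_sum_p(ranks, a.size, w_a)
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return w_a, float(res.pvalue)


def star_code(p: float) -> Stars:
    """Significance stars at the strict thresholds 0.05 / 0.01 / 0.001."""
    if not 0.0 <= p <= 1.0:
        raise ValidationError("p-value outside [0, 1]")
    if p < 0.001:
        return Stars.THREE
    if p < 0.01:
        return Stars.TWO
    if p < 0.05:
        return Stars.ONE
    return Stars.NS


def compare_to_control(
    line_logs: list[ApproachLog],
    control_logs: list[ApproachLog],
    metrics: tuple[str, ...] = ("frac_attempt", "frac_cross"),
    holm: bool = False,
) -> list[GroupComparison]:
    """Per-width, per-metric rank-sum comparisons of a line against control.

    No multiple-testing correction by default (uncorrected per-width stars);
    ``holm=True`` applies a Holm step-down adjustment across the family.
    """
    by_width_line = {log.setup.gap_width: log for log in line_logs}
    by_width_ctrl = {log.setup.gap_width: log for log in control_logs}
    comparisons: list[GroupComparison] = []
    for width in sorted(by_width_line):
        if width not in by_width_ctrl:
            warnings.warn(f"no control data at {width} mm; skipped", stacklevel=2)
            continue
        line_stats = per_fly_fractions(by_width_line[width])
        ctrl_stats = per_fly_fractions(by_width_ctrl[width])
        for metric in metrics:
            a = [getattr(s, metric) for s in line_stats]
            b = [getattr(s, metric) for s in ctrl_stats]
            w, p = rank_sum_test(a, b)
            comparisons.append(GroupComparison(width, metric, w, p, star_code(p)))
    if holm:
        order = sorted(range(len(comparisons)), key=lambda i: comparisons[i].p_value)
        m = len(comparisons)
        adj_prev = 0.0
        adjusted = [0.0] * m
        for rank, i in enumerate(order):
            adj = min(1.0, (m - rank) * comparisons[i].p_value)
            adj_prev = max(adj_prev, adj)
            adjusted[i] = adj_prev
        comparisons = [
            GroupComparison(c.gap_width, c.metric, c.statistic, padj, star_code(padj))
            for c, padj in zip(comparisons, adjusted)
        ]
    return comparisons
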