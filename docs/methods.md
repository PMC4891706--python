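# Methods

## Arena and assay geometry

The climbing disk is modelled as a circle of radius `R = 69 mm` (height
15 mm, ceiling gap 3 mm — both recorded but inert at 1 Hz resolution) with
a central recess and five concentric water-filled groove annuli of widths
2.0, 2.5, 3.0, 3.5 and 4.0 mm. Only the disk diameter and groove widths are
published; the radial layout is configurable and defaults to a 10 mm recess
radius with 7.5 mm lands between the recess and each groove (groove inner
radii 17.5, 27.0, 37.0, 47.5 and 58.5 mm), which leaves a 6.5 mm outer land
at the rim — five equal 7.5 mm lands plus the grooves cannot fit exactly
inside 69 mm, so the rim land absorbs the remainder. The catwalk is a
30 × 10 × 4 mm walkway with one rectangular gap (2.0–6.0 mm wide, 5 mm
deep) under one of three visibility conditions (dark, clear, striped).
Coordinates are millimetres, origin at the disk centre, y up; time starts
at glass lift and all intervals are closed at their start.

## The decision model

The perceived ("effective") gap width is `w_eff = w / (g · c)`: the
parallax signal scales multiplicatively with a perception gain `g`
(dimensionless, 1 for controls; 1.6 for the blocked-feedback profiles,
0.6 for the activated ones, 0.8 for the intermediate 27 °C variant) and a
contrast factor `c` per visibility condition (dark 1.0; clear 0.2; striped
1.5; the clear and striped values are free defaults chosen so that the
clear wall saturates the decision while stripes measurably enhance it).
A stronger signal makes the far edge loom closer, hence larger `g` or `c`
shrinks `w_eff`.

The per-approach attempt probability is a piecewise-linear, non-increasing
curve in `w_eff`, clamped to its knot range and to [0, 1]. The control
curve has knots (2.5 mm, 0.80) — the assay's printed anchor — and
(6.0 mm, 0.15), a free parameter consistent with the roughly linear decline
of attempts with width.

Outcomes depend on true width only. Each profile carries a success curve
giving the *per-approach* crossing probability at control perception
(control knots (2.5, 0.70) and (4.0, 18/440); super-climber (2.5, 0.75)
and (4.0, 40/300)); the per-attempt crossing probability is obtained by
dividing by the attempt curve evaluated at the *true* width, which makes
per-attempt success independent of `g` and `c` by construction — blocking
or activating the perception pathway changes how often flies try, not how
those tries end. Falls are drawn first at the per-attempt fall probability
(a profile constant: 0.5 "clumsy", 0.13 tarsal-grip defect, 0.01 control
— the control value is a free default keeping a 10-minute run's losses in
the low single digits out of 15; 0.005 super climber, matching its
unchanged death rate; 0 overcautious, whose few attempts all stay dry),
and crossing is renormalised by `1/(1 − p_fall)` so the per-approach
marginal is preserved. The tarsal-defect profile's success curve is the
control curve scaled by 0.87 so the renormalised crossing probability
stays a probability.

## The ring-assay simulator

Fifteen flies wake at uniform-area random positions in the recess and
perform a correlated random walk at 1 Hz: each second the heading is
redrawn uniformly with probability `p0 / (1 + t/τ)` (defaults `p0 = 0.4`,
`τ = 60 s` — paths straighten over time, driving outward dispersal),
the fly advances at a truncated-normal speed (mean 6 mm/s, s.d. 2 mm/s)
and reflects off the disk rim. A step that would carry a fly into a groove
annulus stops at the near edge and triggers a decision at
`attempt_probability(w_eff)`. Declining flies turn away from the edge with
tangential jitter; an attempt either drowns the fly (position frozen at the
groove midline at its approach azimuth, status dead, still contributing to
the mean distance), carries it across (a 3 s stationary "traverse" then
reappearance at the far edge — only 1 Hz positions are analysed downstream,
so crossing kinematics are not modelled), or ends in a retreat. After any
decision a 20 s refractory deflects further groove encounters without a
fresh decision: without it, 1 Hz edge-to-edge ping-pong between 7.5 mm
lands would produce >100 decisions per fly per run and near-certain
drowning at any realistic fall rate; with it a control fly makes on the
order of 20–30 decisions in 10 minutes and control losses stay around
1–3 of 15. Decisions are symmetric in direction (inward crossings are
gated identically).

Randomness comes from one `numpy` Philox/PCG stream family: each fly's
generator is seeded with the tuple (experiment seed, replicate, fly id),
so records are byte-identical across reruns and stable per fly when the
cohort changes.

## Analysis definitions

- Relative distance: `r(t) = √(x²+y²)/R ∈ [0, 1]`; the mean-distance
  series averages all 15 flies per second, dead flies contributing their
  frozen positions.
- The maximum mean distance takes the *first* attaining time (ties broken
  toward earlier t; the assay definition is silent on ties).
- Death detection from tracks alone: a fly is dead iff from some time to
  the end of the recording it remains inside a single groove annulus with
  total path length under ε = 0.5 mm. Live flies never rest inside a
  water-filled annulus, so a final sample inside one counts even when the
  fall happens on the last second. On simulated data this reproduces the
  simulator's ground-truth status exactly; on camera-derived tracks it
  stands in for the original manual end-of-run count.
- Walking activity: mean per-second displacement over alive fly-seconds
  (both endpoints alive), in mm/s; 0 when no such seconds exist. The
  original screen's exact activity formula is unpublished, so the metric
  definition is embedded in the output metadata.
- Tracks are used as recorded: missing samples are an error, never imputed.

## Classification

Per line, the medians over replicates of the maximum mean distance (x) and
the drowned percentage (y, multiples of 100/15) feed a decision ladder
against population boundaries: the 10th/90th percentiles of the line
x-medians and the 90th percentile of the y-medians, all computed by linear
interpolation of order statistics (`numpy.percentile` default). Boundary
comparisons are inclusive (≤ x_low, ≥ x_high, ≥ y_high): on the discrete
death statistic, ties at the boundary are all flagged, so the high-death
classes can exceed 10% in tied populations while continuous tie-free
populations split exactly 10/80/10. There is deliberately no low-death
category. Controls are summarised separately (median/quartile/decile cross)
and take no part in boundary placement.

## Single-gap statistics

Per-fly fractions are counts over exactly 10 approaches; falls are reported
both per approach and per attempt (the falls-among-attempts reading matches
how fall rates are quoted for the motor-defect phenotypes). Box summaries
are median, 25/75 quartiles and 10/90 deciles under the same quantile
convention. The Wilcoxon rank-sum test enumerates all label assignments
(with midranks for ties) when the pooled sample size is ≤ 20 — group sizes
of ~10 + 10 straddle the normal-approximation regime, and C(20,10) ≈ 1.8×10⁵
splits enumerate instantly — and otherwise uses the tie- and
continuity-corrected normal approximation (`scipy.stats.mannwhitneyu`,
which also serves as an independent oracle for the exact path in the test
suite). The two-sided p is `min(1, 2·min(P(W≤w), P(W≥w)))`; all-tied
pooled data yields p = 1. Stars follow strict thresholds (\* <0.05,
\*\* <0.01, \*\*\* <0.001) with no multiple-testing correction by default
(per-width stars are quoted uncorrected in this assay); a Holm step-down
option exists.

## Synthetic camera stage

Frames are rendered at 0.2 mm/px: bright field (1.0), groove annuli 0.8,
flies as 2.6 × 1.2 mm dark ellipses (0.15). Detection thresholds at a fixed
0.5 by default — Otsu (available as an option) splits background from the
large groove annuli rather than from the small fly blobs — then filters
connected components by a 15–2000 px area band, which rejects groove annuli
(>5000 px) while keeping merged fly clusters. A drowned fly inside a groove
stays darker than the groove and remains detectable. Linking is greedy
nearest-neighbour with a 15 mm gate (the largest plausible 1 s
displacement), carrying unmatched tracks as stationary and re-attaching
leftover detections to the nearest free track after merges; tracks first
seen later (flies separating from the initial recess clump) are backfilled
with their first detected position. Identity swaps are tolerated by design:
the screen statistics are means over flies. The render→detect→link→analyse
round trip reproduces the direct maximum mean distance to ~5×10⁻⁴ relative
units, well inside the 0.02 tolerance asserted in the tests.

## What the synthetic data do and do not show

The generator reproduces the statistical skeleton the analysis relies on —
width-dependent attempt rates with the printed control anchors,
perception-gain and contrast modulation, outcome rates tied to true width,
drowning that freezes positions, 1 Hz sampling of 15-fly cohorts — but not
real fly kinematics (no grooming, wall-following, inter-fly interaction or
sub-second structure), no imaging noise or illumination gradients, and no
identity-tracking pathologies beyond blob merging. Passing tests therefore
validate the *analysis definitions and statistics* against known ground
truth, not the biological fidelity of any particular parameter; headline
screen percentages from the original 2,415-line data set are not
reproducible without the unpublished raw data.

## Problem sizes and numerical choices

The test suite runs cohorts of 15–200 flies, 100–200 replicate simulations
for Monte-Carlo envelopes and detector/ground-truth equivalence, a
200-line continuous population for the quantile-partition identities, and
20 seeds for the camera round trip (120–600 s runs). The binomial-median
recovery check uses 101-fly cohorts: with even cohorts the two middle
order statistics straddle adjacent binomial values often enough to blur
the median, while any odd cohort ≥ 101 pins it. `scripts/acceptance.py`
uses 50-fly sessions for the 2.5 mm control medians, 201-fly sessions for
the 4.0 mm medians (whose binomial medians sit on wide plateaus) and
≥ 6000 accumulated attempts for the fall-rate estimate (binomial s.e.
≈ 0.4 points). Probability interpolation clamps to [0, 1]; groove-edge
stand-off is 10⁻⁶ mm; equality comparisons on quantiles use exact float
arithmetic since all inputs are multiples of 1/10.
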