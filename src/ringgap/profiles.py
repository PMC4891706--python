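"""Behaviour profiles and the perception-gain decision model.

Flies estimate gap width from the parallax motion of the distal gap edge
during approach. The model treats manipulations of that pathway (silencing or
depolarising the C2/C3 feedback neurons, changing the optical contrast of the
distal wall) as multiplicative changes of the perceived signal: the gap is
acted upon at its *effective* width

    w_eff = w / (g * c)

where ``g`` is the perception gain (1 for controls, >1 when inhibitory
feedback is blocked so parallax appears stronger and the far edge closer,
<1 under activation) and ``c`` a per-visibility contrast factor (1 for a
solid dark block, <1 for a translucent one, >1 for a striped wall).

The probability of initiating a climb falls roughly linearly with gap width;
it is modelled as a piecewise-linear, non-increasing curve in ``w_eff``.
Outcomes of an attempt (crossing, falling) depend on the *true* width only:
perception decides whether to try, biomechanics decides how it ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import Visibility


class ConfigurationError(ValueError):
    """Raised when a profile or parameter set violates its invariants."""


@dataclass(frozen=True)
class PerceptionParams:
    """Multiplicative parallax-perception model parameters.

    gain: 1 = control; >1 enhanced parallax (C2/C3 block); <1 attenuated
    (C2/C3 activation). contrast_* scale the signal per visibility condition.
    """

    gain: float = 1.0
    contrast_dark: float = 1.0
    contrast_clear: float = 0.2
    contrast_striped: float = 1.5

    def __post_init__(self) -> None:
        for name in ("gain", "contrast_dark", "contrast_clear", "contrast_striped"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")

    def contrast(self, visibility: Visibility | str) -> float:
        return {
            Visibility.DARK: self.contrast_dark,
            Visibility.CLEAR: self.contrast_clear,
            Visibility.STRIPED: self.contrast_striped,
        }[Visibility(visibility)]


Curve = tuple[tuple[float, float], ...]


def _validate_curve(curve: Curve, name: str) -> Curve:
    if not curve:
        raise ConfigurationError(f"{name} must have at least one knot")
    curve = tuple((float(w), float(p)) for w, p in curve)
    widths = [w for w, _ in curve]
    probs = [p for _, p in curve]
    if any(b <= a for a, b in zip(widths, widths[1:])):
        raise ConfigurationError(f"{name} knot widths must be strictly increasing")
    if any(not 0.0 <= p <= 1.0 for p in probs):
        raise ConfigurationError(f"{name} probabilities must lie in [0, 1]")
    if any(b > a for a, b in zip(probs, probs[1:])):
        raise ConfigurationError(f"{name} must be non-increasing in width")
    return curve


def interp_curve(curve: Curve, w: float) -> float:
    """Piecewise-linear interpolation, clamped to the knot range and [0, 1]."""
    widths = np.array([k[0] for k in curve])
    probs = np.array([k[1] for k in curve])
    return float(np.clip(np.interp(w, widths, probs), 0.0, 1.0))


@dataclass(frozen=True)
class BehaviorProfile:
    """Per-line simulation parameters.

    ``attempt_curve`` gives the probability of a climbing attempt per
    approach as a function of effective width at control scale;
    ``success_curve`` the per-approach crossing probability as a function of
    true width at control perception (gain = contrast = 1). Speeds are mm/s,
    the turn probability decays hyperbolically from ``turn_rate_initial``
    with timescale ``persistence_timescale`` seconds, crossings occupy
    ``crossing_duration`` seconds.
    """

    name: str
    attempt_curve: Curve
    success_curve: Curve
    fall_given_attempt: float = 0.0
    perception: PerceptionParams = field(default_factory=PerceptionParams)
    speed_mean: float = 6.0
    speed_sd: float = 2.0
    turn_rate_initial: float = 0.4
    persistence_timescale: float = 60.0
    crossing_duration: float = 3.0
    #: seconds after a groove decision during which new encounters are
    #: deflected without a fresh decision (flies do not re-approach
    #: immediately after retreating or crossing)
    approach_refractory: float = 20.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "attempt_curve", _validate_curve(self.attempt_curve, "attempt_curve"))
        object.__setattr__(self, "success_curve", _validate_curve(self.success_curve, "success_curve"))
        if not 0.0 <= self.fall_given_attempt <= 1.0:
            raise ConfigurationError("fall_given_attempt must lie in [0, 1]")
        if self.speed_mean <= 0:
            raise ConfigurationError("speed_mean must be positive")
        if self.speed_sd < 0:
            raise ConfigurationError("speed_sd must be non-negative")
        if not 0.0 <= self.turn_rate_initial <= 1.0:
            raise ConfigurationError("turn_rate_initial must lie in [0, 1]")
        if self.persistence_timescale <= 0 or self.crossing_duration < 0:
            raise ConfigurationError("timescales must be positive")
        if self.approach_refractory < 0:
            raise ConfigurationError("approach_refractory must be non-negative")


def effective_width(w: float, perception: PerceptionParams,
                    visibility: Visibility | str = Visibility.DARK) -> float:
    """Perceived gap width: true width divided by gain × contrast.

    Strictly decreasing in both gain and contrast; equals ``w`` for a
    control fly (gain 1) at normal contrast (dark block, contrast 1).
    """
    if w <= 0:
        raise ConfigurationError("gap width must be positive")
    return w / (perception.gain * perception.contrast(visibility))


def attempt_probability(w_eff: float, profile: BehaviorProfile) -> float:
    """Probability of a climbing attempt per approach at effective width."""
    if w_eff <= 0:
        raise ConfigurationError("effective width must be positive")
    return interp_curve(profile.attempt_curve, w_eff)


def outcome_probabilities(w_true: float, profile: BehaviorProfile) -> tuple[float, float]:
    """(per-approach crossing probability, per-attempt fall probability).

    Both depend on the true width only: the crossing probability is the
    profile's success curve at ``w_true`` (the marginal over approaches at
    control perception) and the fall probability is the profile constant.
    """
    if w_true <= 0:
        raise ConfigurationError("gap width must be positive")
    return interp_curve(profile.success_curve, w_true), profile.fall_given_attempt


def attempt_outcome_probs(w_true: float, profile: BehaviorProfile) -> tuple[float, float]:
    """Per-attempt outcome probabilities ``(p_fall, p_cross_given_no_fall)``.

    Converts the per-approach success marginal into the per-attempt
    conditional by dividing by the attempt probability at the *true* width,
    so per-attempt success does not depend on perception gain or contrast.
    Falls are drawn first; crossing is renormalised by ``1 - p_fall`` so the
    per-approach marginal is preserved.
    """
    p_cross_approach, p_fall = outcome_probabilities(w_true, profile)
    p_attempt_true = interp_curve(profile.attempt_curve, w_true)
    if p_attempt_true <= 0.0:
        return p_fall, 0.0
    p_cross_given_attempt = min(1.0, p_cross_approach / p_attempt_true)
    if p_fall >= 1.0:
        return 1.0, 0.0
    return p_fall, min(1.0, p_cross_given_attempt / (1.0 - p_fall))


# ---------------------------------------------------------------------------
# Packaged line profiles.
#
# Printed anchors: control attempt 80% and success 70% per approach at
# 2.5 mm; control success 18/440 and super-climber success 40/300 per
# approach at 4.0 mm; tarsi-defect falls in 13% of attempts; strong "clumsy"
# lines fall in about half of their attempts. All other knot values are free
# defaults chosen for the roughly linear decline of attempts with width.
# ---------------------------------------------------------------------------

CONTROL_ATTEMPT = ((2.5, 0.80), (6.0, 0.15))
CONTROL_SUCCESS = ((2.5, 0.70), (4.0, 18 / 440))

# controls do drown occasionally (the screen's control cross sits at a
# nonzero death percentage, with most losses at the broad gaps); a 1%
# per-attempt fall rate keeps a 10-minute run's losses in the low single
# digits out of 15 flies, the free default for an unprinted quantity
_control = BehaviorProfile(
    name="control",
    attempt_curve=CONTROL_ATTEMPT,
    success_curve=CONTROL_SUCCESS,
    fall_given_attempt=0.01,
)

PROFILES: dict[str, BehaviorProfile] = {
    "control": _control,
    # barely leaves the recess, attempts rare but usually succeed, none fall
    "overcautious": replace(
        _control,
        name="overcautious",
        attempt_curve=((2.5, 0.15), (6.0, 0.02)),
        success_curve=((2.5, 0.13), (4.0, 0.005)),
        fall_given_attempt=0.0,
        speed_mean=2.0,
        turn_rate_initial=0.7,
    ),
    # motor defect: half of all attempts end in the water
    "clumsy": replace(
        _control,
        name="clumsy",
        fall_given_attempt=0.5,
        success_curve=((2.5, 0.35), (4.0, 0.02)),
    ),
    # tarsal-grip defect: 13% of attempts slip and fall
    "tarsi_clumsy": replace(
        _control,
        name="tarsi_clumsy",
        fall_given_attempt=0.13,
        success_curve=tuple((w, p * (1 - 0.13)) for w, p in CONTROL_SUCCESS),
    ),
    # C2/C3 block: enhanced parallax, gaps look narrower, more attempts
    "overeager": replace(
        _control,
        name="overeager",
        perception=PerceptionParams(gain=1.6),
    ),
    # C2/C3 depolarisation: attenuated parallax, gaps look wider
    "c2_activated": replace(
        _control,
        name="c2_activated",
        perception=PerceptionParams(gain=0.6),
    ),
    # graded activation at 27 °C: intermediate attenuation
    "c2_activated_27C": replace(
        _control,
        name="c2_activated_27C",
        perception=PerceptionParams(gain=0.8),
    ),
    # crosses even the 4.0 mm groove more often than most lines, with no
    # increase in death rate despite the extra attempts
    "super_climber": replace(
        _control,
        name="super_climber",
        attempt_curve=((2.5, 0.90), (6.0, 0.40)),
        success_curve=((2.5, 0.75), (4.0, 40 / 300)),
        fall_given_attempt=0.005,
        speed_mean=8.0,
    ),
}


def get_profile(name: str) -> BehaviorProfile:
    try:
        return PROFILES[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown profile {name!r}; available: {sorted(PROFILES)}"
        ) from None
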