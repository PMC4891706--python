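"""Agent-based simulation of the ring-gap and single-gap assays.

Ring assay: 15 cold-anaesthetised flies wake in the central recess of the
climbing disk and disperse for 10 minutes while an overhead camera logs
positions once per second. Dispersal is a correlated random walk whose
turning probability decays over time (path increments straighten as the
flies move out). Whenever a fly reaches the inner edge of a water-filled
groove it decides whether to attempt a climb based on the *effective*
(perceived) width; an attempt either carries it across (a timed traverse),
ends in the water (the fly drowns and its position freezes at the groove
midline, continuing to contribute to the mean distance), or is aborted.
Declining flies turn back inward.

Single-gap assay: each fly is scored over 10 voluntary approaches to one
rectangular gap; each approach yields attempted / fell / crossed flags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import ArenaGeometry, CatwalkSetup, Visibility
from .profiles import (
    BehaviorProfile,
    ConfigurationError,
    attempt_outcome_probs,
    attempt_probability,
    effective_width,
    get_profile,
)

_EDGE_EPS = 1e-6  # stand-off from groove edges, mm


class ValidationError(ValueError):
    """Raised when simulated or loaded records violate their invariants."""


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass
class FlyTrack:
    """One fly's 1 Hz trajectory with per-sample alive/dead status."""

    fly_id: int
    t: np.ndarray          # seconds, 0..duration-1
    x: np.ndarray          # mm
    y: np.ndarray          # mm
    dead: np.ndarray       # bool per sample; monotone (no resurrection)
    death_groove: int | None = None   # 0-based groove index
    death_time: int | None = None

    def validate(self) -> None:
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.dead) == n):
            raise ValidationError("track arrays must share one length")
        if not np.array_equal(self.t, np.arange(n)):
            raise ValidationError("timestamps must be 0,1,...,duration-1")
        d = self.dead.astype(int)
        if np.any(np.diff(d) < 0):
            raise ValidationError("status flips dead -> alive")
        if self.dead.any():
            i = int(np.argmax(self.dead))
            if self.death_time is None or self.death_groove is None:
                raise ValidationError("dead track missing death metadata")
            if not (np.all(self.x[i:] == self.x[i]) and np.all(self.y[i:] == self.y[i])):
                raise ValidationError("dead fly must keep its final position")

    @property
    def status(self) -> np.ndarray:
        return np.where(self.dead, "dead", "alive")


@dataclass
class ExperimentRecord:
    """One ring-assay run: 15 fly tracks on a shared 1 Hz grid."""

    line_id: str
    replicate: int
    geometry: ArenaGeometry
    tracks: list[FlyTrack]
    duration: int = 600

    def validate(self) -> None:
        if len(self.tracks) != 15:
            raise ValidationError(f"expected 15 tracks, got {len(self.tracks)}")
        for tr in self.tracks:
            tr.validate()
            if len(tr.t) != self.duration:
                raise ValidationError("track length differs from duration")

    @property
    def n_dead(self) -> int:
        return sum(bool(tr.dead[-1]) for tr in self.tracks)


@dataclass(frozen=True)
class ApproachEvent:
    """One voluntary gap approach: attempt and its outcome."""

    fly_id: int
    approach_index: int   # 1..10
    attempted: bool
    fell: bool
    crossed: bool

    def __post_init__(self) -> None:
        if (self.fell or self.crossed) and not self.attempted:
            raise ValidationError("fell/crossed require an attempt")
        if self.fell and self.crossed:
            raise ValidationError("an approach cannot both fall and cross")


@dataclass
class ApproachLog:
    """All approach events of one single-gap session."""

    line_id: str
    setup: CatwalkSetup
    events: list[ApproachEvent]

    def by_fly(self) -> dict[int, list[ApproachEvent]]:
        out: dict[int, list[ApproachEvent]] = {}
        for ev in self.events:
            out.setdefault(ev.fly_id, []).append(ev)
        return out

    def validate(self, n_approaches: int = 10) -> None:
        for fly_id, evs in self.by_fly().items():
            if len(evs) != n_approaches:
                raise ValidationError(
                    f"fly {fly_id} has {len(evs)} approaches, expected {n_approaches}"
                )


@dataclass(frozen=True)
class SimConfig:
    """Reproducible simulation settings; a fixed seed fixes all output."""

    seed: int
    profile: BehaviorProfile | str = "control"
    n_flies: int = 15
    duration: int = 600
    line_id: str | None = None
    replicate: int = 1

    def resolved_profile(self) -> BehaviorProfile:
        if isinstance(self.profile, str):
            return get_profile(self.profile)
        return self.profile


# ---------------------------------------------------------------------------
# Correlated random walk
# ---------------------------------------------------------------------------

def random_walk_step(
    state: tuple[float, float, float, int],
    profile: BehaviorProfile,
    geometry: ArenaGeometry,
    rng: np.random.Generator,
) -> tuple[float, float, float, int]:
    """Advance an alive fly by one second, ignoring groove decisions.

    ``state`` is ``(x, y, heading, t)``. With probability
    ``p0 / (1 + t/tau)`` the heading is redrawn uniformly, otherwise kept;
    the fly advances by one second at a truncated-normal speed and is
    reflected at the disk rim. Groove encounters are resolved by the caller
    (``simulate_ring_experiment``); this kernel never kills a fly.
    """
    x, y, heading, t = state
    p_turn = profile.turn_rate_initial / (1.0 + t / profile.persistence_timescale)
    if rng.random() < p_turn:
        heading = rng.uniform(0.0, 2.0 * math.pi)
    speed = max(0.0, rng.normal(profile.speed_mean, profile.speed_sd))
    nx = x + speed * math.cos(heading)
    ny = y + speed * math.sin(heading)
    r = math.hypot(nx, ny)
    if r > geometry.disk_radius:
        # radial reflection at the rim wall, heading turned back
        scale = (2.0 * geometry.disk_radius - r) / r
        nx, ny = nx * scale, ny * scale
        heading = (heading + math.pi) % (2.0 * math.pi)
    return nx, ny, heading, t + 1


def _fly_rng(seed: int, replicate: int, fly_id: int) -> np.random.Generator:
    # fixed-offset substreams: stable per fly under changed n_flies
    return np.random.default_rng([seed, replicate, fly_id])


def _simulate_fly(
    fly_id: int,
    config: SimConfig,
    geometry: ArenaGeometry,
    profile: BehaviorProfile,
) -> FlyTrack:
    rng = _fly_rng(config.seed, config.replicate, fly_id)
    duration = config.duration
    xs = np.empty(duration)
    ys = np.empty(duration)
    dead = np.zeros(duration, dtype=bool)

    # wake at a uniform-area position inside the recess
    r0 = geometry.recess_radius * math.sqrt(rng.random())
    a0 = rng.uniform(0.0, 2.0 * math.pi)
    x, y = r0 * math.cos(a0), r0 * math.sin(a0)
    heading = rng.uniform(0.0, 2.0 * math.pi)
    xs[0], ys[0] = x, y

    death_groove: int | None = None
    death_time: int | None = None
    hold = 0              # remaining seconds of an ongoing traverse
    hold_target: tuple[float, float] | None = None
    refract = 0           # seconds until the next groove decision is allowed

    inner = geometry.groove_inner_radii
    outer = geometry.groove_outer_radii

    for t in range(1, duration):
        if death_time is not None:
            xs[t], ys[t] = x, y
            dead[t] = True
            continue
        if hold > 0:
            hold -= 1
            if hold == 0 and hold_target is not None:
                x, y = hold_target
                hold_target = None
            xs[t], ys[t] = x, y
            continue

        nx, ny, heading, _ = random_walk_step((x, y, heading, t - 1), profile, geometry, rng)
        r_old = math.hypot(x, y)
        r_new = math.hypot(nx, ny)
        if refract > 0:
            refract -= 1

        # first groove whose annulus the radial move enters
        gi: int | None = None
        outward = r_new >= r_old
        if outward:
            for i in range(len(inner)):
                if r_old < inner[i] and r_new > inner[i] - _EDGE_EPS:
                    gi = i
                    break
        else:
            for i in reversed(range(len(inner))):
                if r_old > outer[i] and r_new < outer[i] + _EDGE_EPS:
                    gi = i
                    break

        if gi is None:
            x, y = nx, ny
            xs[t], ys[t] = x, y
            continue

        # the fly stops at the near edge of the groove
        edge_r = (inner[gi] - _EDGE_EPS) if outward else (outer[gi] + _EDGE_EPS)
        azim = math.atan2(ny, nx)
        x, y = edge_r * math.cos(azim), edge_r * math.sin(azim)
        # turn away from the edge with tangential jitter (edge-following
        # rather than radial ping-pong between neighbouring edges)
        away = (azim + math.pi) if outward else azim
        turn_away = (away + rng.uniform(-1.0, 1.0)) % (2.0 * math.pi)

        if refract > 0:
            heading = turn_away
            xs[t], ys[t] = x, y
            continue

        refract = int(round(profile.approach_refractory))
        w = geometry.groove_widths[gi]
        w_eff = effective_width(w, profile.perception, Visibility.DARK)
        if rng.random() >= attempt_probability(w_eff, profile):
            heading = turn_away
            xs[t], ys[t] = x, y
            continue

        p_fall, p_cross = attempt_outcome_probs(w, profile)
        u = rng.random()
        if u < p_fall:
            mid = geometry.groove_midline(gi)
            x, y = mid * math.cos(azim), mid * math.sin(azim)
            death_groove, death_time = gi, t
            dead[t] = True
        elif rng.random() < p_cross:
            far_r = (outer[gi] + _EDGE_EPS) if outward else (inner[gi] - _EDGE_EPS)
            hold_target = (far_r * math.cos(azim), far_r * math.sin(azim))
            hold = max(1, int(round(profile.crossing_duration)))
        else:
            heading = turn_away
        xs[t], ys[t] = x, y

    return FlyTrack(
        fly_id=fly_id,
        t=np.arange(duration),
        x=xs,
        y=ys,
        dead=dead,
        death_groove=death_groove,
        death_time=death_time,
    )


def simulate_ring_experiment(
    config: SimConfig, geometry: ArenaGeometry | None = None
) -> ExperimentRecord:
    """Simulate one 15-fly, 10-minute ring-assay run at 1 Hz."""
    geometry = geometry or ArenaGeometry()
    profile = config.resolved_profile()
    if config.n_flies != 15:
        raise ConfigurationError("the ring assay uses sets of 15 flies")
    tracks = [
        _simulate_fly(fly_id, config, geometry, profile)
        for fly_id in range(config.n_flies)
    ]
    record = ExperimentRecord(
        line_id=config.line_id or profile.name,
        replicate=config.replicate,
        geometry=geometry,
        tracks=tracks,
        duration=config.duration,
    )
    record.validate()
    return record


# ---------------------------------------------------------------------------
# Single-gap (catwalk) sessions
# ---------------------------------------------------------------------------

def simulate_catwalk_session(
    profile: BehaviorProfile | str,
    setup: CatwalkSetup,
    n_flies: int,
    seed: int,
    n_approaches: int = 10,
    line_id: str | None = None,
) -> ApproachLog:
    """Score ``n_flies`` flies over ``n_approaches`` approaches each.

    Per approach, a climbing attempt is drawn at the probability given by
    the attempt curve evaluated at the effective gap width; given an
    attempt, the fly falls with the profile's per-attempt fall probability,
    otherwise crosses with the per-attempt success probability implied by
    the true width.
    """
    if n_flies < 1:
        raise ConfigurationError("n_flies must be at least 1")
    if isinstance(profile, str):
        profile = get_profile(profile)
    w_eff = effective_width(setup.gap_width, profile.perception, setup.visibility)
    p_attempt = attempt_probability(w_eff, profile)
    p_fall, p_cross = attempt_outcome_probs(setup.gap_width, profile)

    events: list[ApproachEvent] = []
    for fly_id in range(n_flies):
        rng = _fly_rng(seed, 0, fly_id)
        for k in range(1, n_approaches + 1):
            attempted = bool(rng.random() < p_attempt)
            fell = crossed = False
            if attempted:
                if rng.random() < p_fall:
                    fell = True
                elif rng.random() < p_cross:
                    crossed = True
            events.append(ApproachEvent(fly_id, k, attempted, fell, crossed))
    log = ApproachLog(line_id=line_id or profile.name, setup=setup, events=events)
    log.validate(n_approaches)
    return log
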