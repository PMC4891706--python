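"""Primary-screen kinematics from 1 Hz ring-assay track tables.

The screen's classification parameters per experiment are: the maximum of
the per-second mean distance of the 15 flies from the disk centre (in
relative units of the disk radius, dead flies contributing their frozen
final position), the time at which that maximum is first reached, the
percentage of flies that drowned, the per-groove death counts, and the mean
walking activity of the live flies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ArenaGeometry
from .simulate import ExperimentRecord, FlyTrack, ValidationError

#: immobility tolerance for automated death detection, mm of total
#: displacement over the candidate dead interval
DEATH_EPSILON_MM = 0.5


@dataclass
class RingAssayMetrics:
    """Kinematic classification parameters of one ring-assay experiment."""

    line_id: str
    replicate: int
    mean_distance_series: np.ndarray   # relative units, one value per second
    max_mean_distance: float
    time_to_max: int
    dead_per_groove: tuple[int, ...]
    pct_dead: float
    walking_activity: float            # mm/s over alive fly-seconds

    def to_dict(self) -> dict:
        return {
            "line_id": self.line_id,
            "replicate": self.replicate,
            "max_mean_distance": self.max_mean_distance,
            "time_to_max": self.time_to_max,
            "dead_per_groove": list(self.dead_per_groove),
            "pct_dead": self.pct_dead,
            "walking_activity": self.walking_activity,
            # the per-parameter definitions not fixed by the assay itself
            "definitions": {
                "walking_activity": "mean per-second displacement over alive fly-seconds",
                "time_to_max": "first attainment of the maximum mean distance",
                "death_detection": f"immobile in one groove annulus to end of recording, displacement < {DEATH_EPSILON_MM} mm",
            },
        }


def radial_distance_series(track: FlyTrack, geometry: ArenaGeometry) -> np.ndarray:
    """Distance from centre per sample, relative units (0 centre, 1 rim)."""
    r = np.hypot(track.x, track.y)
    if np.any(r > geometry.disk_radius * (1 + 1e-9)):
        raise ValidationError(f"fly {track.fly_id} recorded outside the disk")
    return r / geometry.disk_radius


def mean_distance_series(record: ExperimentRecord) -> np.ndarray:
    """Per-second mean relative distance of all 15 flies from centre.

    Dead flies keep contributing with their frozen final position.
    """
    record.validate()
    rel = np.stack([radial_distance_series(tr, record.geometry) for tr in record.tracks])
    if rel.shape[1] != record.duration:
        raise ValidationError("missing samples in track grid")
    return rel.mean(axis=0)


def max_mean_distance_and_time(series: np.ndarray) -> tuple[float, int]:
    """Maximum of the mean-distance series and the first time it is reached."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValidationError("empty mean-distance series")
    i = int(np.argmax(series))   # argmax returns the first maximiser
    return float(series[i]), i


def detect_deaths_from_tracks(
    track: FlyTrack,
    geometry: ArenaGeometry,
    epsilon: float = DEATH_EPSILON_MM,
) -> tuple[bool, int | None, int | None]:
    """Automated drowning detection: ``(is_dead, groove_index, death_time)``.

    A fly is scored dead iff from some time to the end of the recording it
    sits inside a single groove annulus and its total path length over that
    interval is below ``epsilon``. This reproduces the simulator's written
    status exactly on simulated data; on tracker output it stands in for the
    manual end-of-experiment dead count.
    """
    r = np.hypot(track.x, track.y)
    groove = geometry.groove_at_radius(float(r[-1]))
    if groove is None:
        return False, None, None
    ri = geometry.groove_inner_radii[groove]
    ro = geometry.groove_outer_radii[groove]
    in_groove = (r >= ri) & (r <= ro)
    step = np.hypot(np.diff(track.x), np.diff(track.y))
    n = len(r)
    # earliest t* from which the fly stays in this annulus and barely moves;
    # a live fly never rests inside a water-filled annulus, so ending there
    # counts even if it happened on the final second
    t_star = n - 1
    for t in range(n - 2, -1, -1):
        if in_groove[t] and step[t:].sum() < epsilon:
            t_star = t
        else:
            break
    return True, groove, t_star


def walking_activity(record: ExperimentRecord) -> float:
    """Mean per-second displacement (mm/s) over all alive fly-seconds.

    A fly-second counts as alive when the fly is alive at both its
    endpoints; dead flies contribute nothing after death.
    """
    total = 0.0
    n_alive = 0
    for tr in record.tracks:
        alive_pair = ~tr.dead[1:] & ~tr.dead[:-1]
        step = np.hypot(np.diff(tr.x), np.diff(tr.y))
        total += step[alive_pair].sum()
        n_alive += int(alive_pair.sum())
    return total / n_alive if n_alive else 0.0


def analyze_ring_experiment(record: ExperimentRecord) -> RingAssayMetrics:
    """All primary-screen parameters for one experiment, from tracks alone."""
    series = mean_distance_series(record)
    max_mean, t_max = max_mean_distance_and_time(series)
    n_grooves = record.geometry.n_grooves
    dead_per_groove = [0] * n_grooves
    n_dead = 0
    for tr in record.tracks:
        is_dead, groove, _ = detect_deaths_from_tracks(tr, record.geometry)
        if is_dead:
            n_dead += 1
            dead_per_groove[groove] += 1
    return RingAssayMetrics(
        line_id=record.line_id,
        replicate=record.replicate,
        mean_distance_series=series,
        max_mean_distance=max_mean,
        time_to_max=t_max,
        dead_per_groove=tuple(dead_per_groove),
        pct_dead=100.0 * n_dead / len(record.tracks),
        walking_activity=walking_activity(record),
    )
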