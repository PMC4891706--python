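import numpy as np
import pytest

from ringgap import ArenaGeometry, ExperimentRecord, FlyTrack, get_profile


@pytest.fixture
def geometry():
    return ArenaGeometry()


@pytest.fixture
def control():
    return get_profile("control")


def make_track(fly_id, positions, dead_from=None, death_groove=None):
    """Build a FlyTrack from a list of (x, y); optionally dead from index."""
    n = len(positions)
    x = np.array([p[0] for p in positions], dtype=float)
    y = np.array([p[1] for p in positions], dtype=float)
    dead = np.zeros(n, dtype=bool)
    death_time = None
    if dead_from is not None:
        dead[dead_from:] = True
        death_time = dead_from
        x[dead_from:] = x[dead_from]
        y[dead_from:] = y[dead_from]
    return FlyTrack(
        fly_id=fly_id, t=np.arange(n), x=x, y=y, dead=dead,
        death_groove=death_groove, death_time=death_time,
    )


def make_record(tracks, geometry=None, line_id="debug", duration=None):
    geometry = geometry or ArenaGeometry()
    duration = duration if duration is not None else len(tracks[0].t)
    return ExperimentRecord(
        line_id=line_id, replicate=1, geometry=geometry,
        tracks=tracks, duration=duration,
    )
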