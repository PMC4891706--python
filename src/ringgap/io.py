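"""Readers and writers for the package's plain-text data dialects.

Track table: CSV ``t_s,fly_id,x_mm,y_mm,status`` (status alive/dead), one
file per 15-fly experiment, with a JSON sidecar holding line id, replicate,
seed, geometry and profile. Approach log: CSV
``line_id,gap_mm,visibility,fly_id,approach,attempted,fell,crossed`` with
0/1 flags. Profiles and geometry travel as JSON or YAML mappings. All files
are UTF-8 with '.' decimals and mandatory headers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import ArenaGeometry, CatwalkSetup
from .profiles import BehaviorProfile, ConfigurationError, PerceptionParams
from .simulate import (
    ApproachEvent,
    ApproachLog,
    ExperimentRecord,
    FlyTrack,
    ValidationError,
)

TRACK_COLUMNS = ["t_s", "fly_id", "x_mm", "y_mm", "status"]
APPROACH_COLUMNS = [
    "line_id", "gap_mm", "visibility", "fly_id", "approach",
    "attempted", "fell", "crossed",
]


# ---------------------------------------------------------------------------
# Track tables
# ---------------------------------------------------------------------------

def write_track_table(record: ExperimentRecord, path: str | Path) -> None:
    rows = []
    for tr in record.tracks:
        for t, x, y, dead in zip(tr.t, tr.x, tr.y, tr.dead):
            rows.append((int(t), tr.fly_id, f"{x:.4f}", f"{y:.4f}",
                         "dead" if dead else "alive"))
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    df.to_csv(path, index=False)


def read_track_table(
    path: str | Path,
    geometry: ArenaGeometry | None = None,
    line_id: str = "unknown",
    replicate: int = 1,
) -> ExperimentRecord:
    """Load and validate a track CSV into an :class:`ExperimentRecord`."""
    df = pd.read_csv(path)
    if list(df.columns) != TRACK_COLUMNS:
        raise ValidationError(
            f"{path}: expected header {','.join(TRACK_COLUMNS)}, got {','.join(df.columns)}"
        )
    bad_status = set(df["status"]) - {"alive", "dead"}
    if bad_status:
        raise ValidationError(f"{path}: unknown status values {sorted(bad_status)}")
    if not np.all(df["t_s"] == df["t_s"].astype(int)):
        raise ValidationError(f"{path}: timestamps must lie on the 1 Hz grid")
    fly_ids = sorted(df["fly_id"].unique())
    if len(fly_ids) != 15:
        raise ValidationError(f"{path}: expected 15 flies, found {len(fly_ids)}")
    tracks = []
    duration = None
    for fly_id in fly_ids:
        sub = df[df["fly_id"] == fly_id].sort_values("t_s")
        t = sub["t_s"].to_numpy(dtype=int)
        if duration is None:
            duration = len(t)
        dead = (sub["status"] == "dead").to_numpy()
        if np.any(np.diff(dead.astype(int)) < 0):
            raise ValidationError(f"{path}: fly {fly_id} status flips dead -> alive")
        x = sub["x_mm"].to_numpy(dtype=float)
        y = sub["y_mm"].to_numpy(dtype=float)
        death_time = int(np.argmax(dead)) if dead.any() else None
        death_groove = None
        if death_time is not None and geometry is not None:
            death_groove = geometry.groove_at_radius(
                float(np.hypot(x[death_time], y[death_time]))
            )
        track = FlyTrack(
            fly_id=int(fly_id), t=t, x=x, y=y, dead=dead,
            death_groove=death_groove, death_time=death_time,
        )
        if dead.any() and death_groove is None and geometry is not None:
            raise ValidationError(f"{path}: fly {fly_id} died outside any groove")
        track.validate()
        tracks.append(track)
    record = ExperimentRecord(
        line_id=line_id,
        replicate=replicate,
        geometry=geometry or ArenaGeometry(),
        tracks=tracks,
        duration=duration,
    )
    record.validate()
    return record


# ---------------------------------------------------------------------------
# Approach logs
# ---------------------------------------------------------------------------

def write_approach_log(log: ApproachLog, path: str | Path) -> None:
    rows = [
        (log.line_id, log.setup.gap_width, log.setup.visibility.value,
         ev.fly_id, ev.approach_index,
         int(ev.attempted), int(ev.fell), int(ev.crossed))
        for ev in log.events
    ]
    pd.DataFrame(rows, columns=APPROACH_COLUMNS).to_csv(path, index=False)


def read_approach_log(path: str | Path) -> list[ApproachLog]:
    """Load approach-log CSV; one :class:`ApproachLog` per line × width."""
    df = pd.read_csv(path)
    if list(df.columns) != APPROACH_COLUMNS:
        raise ValidationError(
            f"{path}: expected header {','.join(APPROACH_COLUMNS)}"
        )
    logs = []
    for (line_id, gap, vis), sub in df.groupby(
        ["line_id", "gap_mm", "visibility"], sort=True
    ):
        setup = CatwalkSetup(gap_width=float(gap), visibility=vis)
        events = [
            ApproachEvent(
                fly_id=int(r.fly_id), approach_index=int(r.approach),
                attempted=bool(r.attempted), fell=bool(r.fell),
                crossed=bool(r.crossed),
            )
            for r in sub.itertuples()
        ]
        log = ApproachLog(line_id=str(line_id), setup=setup, events=events)
        log.validate()
        logs.append(log)
    return logs


# ---------------------------------------------------------------------------
# Profiles, geometry, manifests
# ---------------------------------------------------------------------------

_PROFILE_KEYS = {f.name for f in dataclasses.fields(BehaviorProfile)}


def profile_to_dict(profile: BehaviorProfile) -> dict:
    d = dataclasses.asdict(profile)
    d["attempt_curve"] = [list(k) for k in profile.attempt_curve]
    d["success_curve"] = [list(k) for k in profile.success_curve]
    return d


def profile_from_dict(data: dict) -> BehaviorProfile:
    unknown = set(data) - _PROFILE_KEYS
    if unknown:
        raise ConfigurationError(f"unknown profile keys: {sorted(unknown)}")
    for key in ("attempt_curve", "success_curve"):
        if key not in data:
            raise ConfigurationError(f"profile is missing {key!r}")
        data = {**data, key: tuple(tuple(k) for k in data[key])}
    if isinstance(data.get("perception"), dict):
        data = {**data, "perception": PerceptionParams(**data["perception"])}
    return BehaviorProfile(**data)


def read_profile(path: str | Path) -> BehaviorProfile:
    """Load a behaviour profile from JSON or YAML, enforcing invariants."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)   # YAML is a JSON superset
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: profile must be a mapping")
    return profile_from_dict(data)


def write_profile(profile: BehaviorProfile, path: str | Path) -> None:
    Path(path).write_text(json.dumps(profile_to_dict(profile), indent=2))


def geometry_to_dict(geometry: ArenaGeometry) -> dict:
    return dataclasses.asdict(geometry)


def read_geometry(path: str | Path) -> ArenaGeometry:
    data = yaml.safe_load(Path(path).read_text())
    return ArenaGeometry(**data)


def write_sidecar(path: str | Path, **metadata) -> None:
    """JSON sidecar next to a data file (line, replicate, seed, config)."""
    Path(path).write_text(json.dumps(metadata, indent=2, default=str))


def run_manifest(command: str, seed: int | None, inputs: list[str],
                 outputs: list[str], config: dict) -> dict:
    """Provenance record written once per CLI invocation."""
    from . import __version__

    config_blob = json.dumps(config, sort_keys=True, default=str)
    return {
        "command": command,
        "seed": seed,
        "inputs": inputs,
        "outputs": outputs,
        "config_sha256": hashlib.sha256(config_blob.encode()).hexdigest(),
        "package_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
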