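"""Overhead-camera emulation: frame rendering, blob detection, linking.

The rig backlights the disk, so flies appear as small dark blobs on a
bright field, with the water-filled groove annuli slightly darker than the
Perspex lands. ``render_frame`` draws that scene at a configurable pixel
pitch; ``detect_blobs`` recovers fly centroids by thresholding and
connected components; ``link_detections`` chains per-frame detections into
1 Hz tracks by greedy nearest-neighbour assignment with a gating radius,
carrying unmatched tracks as stationary (merged or drowned flies).

Identity-accurate tracking is a non-goal: the screen statistics are means
over the 15 flies and are insensitive to identity swaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .geometry import ArenaGeometry
from .simulate import ExperimentRecord, FlyTrack, ValidationError

BACKGROUND_INTENSITY = 1.0
GROOVE_INTENSITY = 0.8
FLY_INTENSITY = 0.15
FLY_SEMI_AXES_MM = (1.3, 0.6)   # ~2.6 mm body length
DEFAULT_PIXEL_PITCH = 0.2       # mm per pixel
DEFAULT_THRESHOLD = 0.5
DEFAULT_SIZE_BAND = (15, 2000)  # pixels; upper bound admits merged clusters
                                # while rejecting groove annuli (>5000 px)
DEFAULT_GATING_RADIUS = 15.0    # mm; max plausible 1 s displacement


@dataclass
class Frame:
    """One rendered overhead image; origin at disk centre, y up."""

    image: np.ndarray
    pixel_pitch: float
    timestamp: float
    extent: float   # half-width of the imaged square, mm

    def to_pixel(self, x: float, y: float) -> tuple[float, float]:
        return (self.extent - y) / self.pixel_pitch, (x + self.extent) / self.pixel_pitch

    def to_mm(self, row: float, col: float) -> tuple[float, float]:
        return col * self.pixel_pitch - self.extent, self.extent - row * self.pixel_pitch


@dataclass(frozen=True)
class Detection:
    x: float      # mm
    y: float      # mm
    area: int     # pixels


def _background(geometry: ArenaGeometry, pixel_pitch: float, extent: float) -> np.ndarray:
    n = int(np.ceil(2 * extent / pixel_pitch))
    coords = (np.arange(n) + 0.5) * pixel_pitch - extent
    xx, yy = np.meshgrid(coords, -coords)   # row 0 at the top (y = +extent)
    r = np.hypot(xx, yy)
    img = np.full((n, n), BACKGROUND_INTENSITY)
    for ri, ro in zip(geometry.groove_inner_radii, geometry.groove_outer_radii):
        img[(r >= ri) & (r <= ro)] = GROOVE_INTENSITY
    return img


def render_frame(
    positions: np.ndarray,
    geometry: ArenaGeometry,
    pixel_pitch: float = DEFAULT_PIXEL_PITCH,
    timestamp: float = 0.0,
    background: np.ndarray | None = None,
) -> Frame:
    """Render one backlit frame with a dark elliptical blob per fly.

    ``positions`` is an (n, 2) array of fly centres in mm. Overlapping
    flies merge into a single blob. ``background`` may be passed to reuse a
    precomputed arena image across frames.
    """
    positions = np.asarray(positions, dtype=float).reshape(-1, 2)
    if positions.size and np.any(np.hypot(positions[:, 0], positions[:, 1]) > geometry.disk_radius):
        raise ValidationError("fly position outside the disk")
    extent = geometry.disk_radius + 5.0
    img = (_background(geometry, pixel_pitch, extent) if background is None
           else background).copy()
    frame = Frame(image=img, pixel_pitch=pixel_pitch, timestamp=timestamp, extent=extent)
    a, b = FLY_SEMI_AXES_MM
    ra = int(np.ceil(a / pixel_pitch)) + 1
    for x, y in positions:
        r0, c0 = frame.to_pixel(x, y)
        rows = np.arange(max(0, int(r0) - ra), min(img.shape[0], int(r0) + ra + 1))
        cols = np.arange(max(0, int(c0) - ra), min(img.shape[1], int(c0) + ra + 1))
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        dx = (cc + 0.5) * pixel_pitch - extent - x
        dy = extent - (rr + 0.5) * pixel_pitch - y
        mask = (dx / a) ** 2 + (dy / b) ** 2 <= 1.0
        img[rr[mask], cc[mask]] = FLY_INTENSITY
    return frame


def detect_blobs(
    frame: Frame,
    threshold: float | str = DEFAULT_THRESHOLD,
    size_band: tuple[int, int] = DEFAULT_SIZE_BAND,
) -> list[Detection]:
    """Fly centroids from connected components below ``threshold``.

    ``threshold="otsu"`` estimates the cut from the image histogram; the
    fixed default separates fly blobs from both the bright field and the
    darker groove annuli. Components outside ``size_band`` (groove annuli,
    noise) are discarded.
    """
    if threshold == "otsu":
        threshold = float(threshold_otsu(frame.image))
    mask = frame.image < threshold
    out = []
    for region in regionprops(label(mask)):
        if not size_band[0] <= region.area <= size_band[1]:
            continue
        x, y = frame.to_mm(*region.centroid)
        out.append(Detection(x=x, y=y, area=int(region.area)))
    return out


def link_detections(
    detections_per_frame: list[list[Detection]],
    n_flies: int = 15,
    gating_radius: float = DEFAULT_GATING_RADIUS,
) -> list[FlyTrack]:
    """Greedy nearest-neighbour linking of detections into ``n_flies`` tracks.

    Within each frame, track-detection pairs are matched closest-first
    inside the gating radius; leftover detections are then attached to the
    nearest unmatched track regardless of gate (recovery after merges).
    Unmatched tracks are carried as stationary (merged or drowned
    candidates). Tracks appearing after the first frame are backfilled with
    their first detected position.
    """
    n_frames = len(detections_per_frame)
    positions: list[np.ndarray] = []   # one (n_flies, 2) array per frame
    active: list[tuple[float, float]] = []
    first_seen: list[int] = []

    for t, dets in enumerate(detections_per_frame):
        if len(dets) > n_flies:
            raise ValidationError(
                f"frame {t}: {len(dets)} detections exceed the {n_flies} configured flies"
            )
        det_xy = [(d.x, d.y) for d in dets]
        matched_det: set[int] = set()
        new_pos = list(active)
        if active and det_xy:
            dist = np.array(
                [[np.hypot(ax - dx, ay - dy) for dx, dy in det_xy] for ax, ay in active]
            )
            free_tracks = set(range(len(active)))
            pairs = sorted(
                ((dist[i, j], i, j) for i in free_tracks for j in range(len(det_xy))),
            )
            for d, i, j in pairs:
                if d > gating_radius:
                    break
                if i in free_tracks and j not in matched_det:
                    new_pos[i] = det_xy[j]
                    free_tracks.discard(i)
                    matched_det.add(j)
            # recovery pass: leftover detections to nearest free track
            for j in range(len(det_xy)):
                if j in matched_det:
                    continue
                if free_tracks and len(active) >= n_flies:
                    i = min(free_tracks, key=lambda i: dist[i, j])
                    new_pos[i] = det_xy[j]
                    free_tracks.discard(i)
                    matched_det.add(j)
        for j in range(len(det_xy)):
            if j not in matched_det and len(new_pos) < n_flies:
                new_pos.append(det_xy[j])
                first_seen.append(t)
        active = new_pos
        positions.append(np.array(active, dtype=float).reshape(-1, 2))

    tracks = []
    for i in range(len(active)):
        xs = np.empty(n_frames)
        ys = np.empty(n_frames)
        for t in range(n_frames):
            if i < len(positions[t]):
                xs[t], ys[t] = positions[t][i]
            else:
                xs[t], ys[t] = positions[first_seen[i]][i]
        tracks.append(
            FlyTrack(
                fly_id=i,
                t=np.arange(n_frames),
                x=xs,
                y=ys,
                dead=np.zeros(n_frames, dtype=bool),
            )
        )
    return tracks


def track_experiment(
    record: ExperimentRecord,
    pixel_pitch: float = DEFAULT_PIXEL_PITCH,
    threshold: float | str = DEFAULT_THRESHOLD,
) -> ExperimentRecord:
    """Round-trip convenience: render a simulated run, detect, and link.

    Returns a new record whose tracks come from the synthetic camera
    pipeline; death status is left unset (downstream analysis detects
    drowned flies from immobility inside a groove annulus).
    """
    geometry = record.geometry
    extent = geometry.disk_radius + 5.0
    bg = _background(geometry, pixel_pitch, extent)
    dets = []
    for t in range(record.duration):
        pos = np.array([[tr.x[t], tr.y[t]] for tr in record.tracks])
        frame = render_frame(pos, geometry, pixel_pitch, timestamp=t, background=bg)
        dets.append(detect_blobs(frame, threshold=threshold))
    tracks = link_detections(dets, n_flies=len(record.tracks))
    for tr in tracks:
        # centroid quantisation can push a rim-hugging fly marginally
        # outside the disk; clamp radially
        r = np.hypot(tr.x, tr.y)
        over = r > geometry.disk_radius
        if over.any():
            scale = geometry.disk_radius / r[over]
            tr.x[over] *= scale
            tr.y[over] *= scale
    while len(tracks) < len(record.tracks):
        # a fly that never separated from a merged blob: duplicate its host
        # position is unknowable; carry the recess centre
        i = len(tracks)
        tracks.append(
            FlyTrack(
                fly_id=i,
                t=np.arange(record.duration),
                x=np.zeros(record.duration),
                y=np.zeros(record.duration),
                dead=np.zeros(record.duration, dtype=bool),
            )
        )
    return ExperimentRecord(
        line_id=record.line_id,
        replicate=record.replicate,
        geometry=geometry,
        tracks=tracks,
        duration=record.duration,
    )
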