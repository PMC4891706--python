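"""Arena and catwalk geometry.

The ring-gap arena is a backlit Perspex disk (Ø 138 mm, 15 mm high) with a
central recess and five concentric water-filled grooves of increasing width
(2.0–4.0 mm in 0.5 mm steps). A glass ceiling 3 mm above the surface prevents
flight. The single-gap ("catwalk") rig is a linear walkway interrupted by one
rectangular gap of configurable width under one of three visibility
conditions.

Coordinates are millimetres with the origin at the disk centre, y up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence


class GeometryError(ValueError):
    """Raised when an arena or catwalk specification is inconsistent."""


DISK_RADIUS_MM = 69.0
DEFAULT_GROOVE_WIDTHS = (2.0, 2.5, 3.0, 3.5, 4.0)

# Radial layout is not dimensioned in print ("drawn to scale" only): the
# packaged default places 7.5 mm lands between the recess and each groove,
# leaving a 6.5 mm land at the rim.
_DEFAULT_RECESS_RADIUS = 10.0


def _default_inner_radii() -> tuple[float, ...]:
    radii = []
    r = _DEFAULT_RECESS_RADIUS
    for w in DEFAULT_GROOVE_WIDTHS:
        r += 7.5
        radii.append(r)
        r += w
    return tuple(radii)


@dataclass(frozen=True)
class ArenaGeometry:
    """Climbing-disk geometry: recess, five groove annuli, rim.

    Groove ``i`` occupies the annulus
    ``groove_inner_radii[i] <= r <= groove_inner_radii[i] + groove_widths[i]``.
    """

    disk_radius: float = DISK_RADIUS_MM
    disk_height: float = 15.0
    recess_radius: float = _DEFAULT_RECESS_RADIUS
    groove_widths: tuple[float, ...] = DEFAULT_GROOVE_WIDTHS
    groove_inner_radii: tuple[float, ...] = field(default_factory=_default_inner_radii)
    ceiling_gap: float = 3.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "groove_widths", tuple(self.groove_widths))
        object.__setattr__(self, "groove_inner_radii", tuple(self.groove_inner_radii))
        w, ri = self.groove_widths, self.groove_inner_radii
        if len(w) != len(ri):
            raise GeometryError("groove_widths and groove_inner_radii length mismatch")
        if self.disk_radius <= 0 or self.recess_radius <= 0:
            raise GeometryError("radii must be positive")
        if any(b <= a for a, b in zip(w, w[1:])):
            raise GeometryError("groove_widths must be strictly increasing")
        outer = [a + b for a, b in zip(ri, w)]
        for i in range(1, len(ri)):
            if ri[i] <= outer[i - 1]:
                raise GeometryError(f"groove annuli {i-1} and {i} overlap")
        if ri and self.recess_radius >= ri[0]:
            raise GeometryError("recess must lie inside the innermost groove")
        if outer and outer[-1] > self.disk_radius:
            raise GeometryError("outermost groove extends beyond the disk rim")

    @property
    def n_grooves(self) -> int:
        return len(self.groove_widths)

    @property
    def groove_outer_radii(self) -> tuple[float, ...]:
        return tuple(a + b for a, b in zip(self.groove_inner_radii, self.groove_widths))

    def groove_midline(self, index: int) -> float:
        """Radius of the centreline of groove ``index`` (0-based)."""
        return self.groove_inner_radii[index] + self.groove_widths[index] / 2.0

    def groove_at_radius(self, r: float) -> int | None:
        """Index of the groove annulus containing radius ``r``, or None."""
        for i, (ri, ro) in enumerate(zip(self.groove_inner_radii, self.groove_outer_radii)):
            if ri <= r <= ro:
                return i
        return None


class Visibility(str, Enum):
    """Visual condition of the gap's distal side on the catwalk."""

    DARK = "dark"        # solid dark block: normal contrast
    CLEAR = "clear"      # translucent Perspex: weak parallax signal
    STRIPED = "striped"  # vertical stripes on the distal wall: enhanced signal


@dataclass(frozen=True)
class CatwalkSetup:
    """Single-gap walkway: one rectangular gap crossed voluntarily."""

    gap_width: float
    visibility: Visibility = Visibility.DARK
    length: float = 30.0
    height: float = 10.0
    width: float = 4.0
    gap_depth: float = 5.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "visibility", Visibility(self.visibility))
        if not 0 < self.gap_width:
            raise GeometryError("gap_width must be positive")
        if not 2.0 <= self.gap_width <= 6.0:
            raise GeometryError("gap_width must lie in [2.0, 6.0] mm")
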