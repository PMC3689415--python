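"""Screen geometry and angular <-> pixel coordinate conversions.

The projection screen is modelled by its physical size, pixel resolution and
the viewing distance.  Angles use the small-angle (arc length / distance)
convention, i.e. an extent of ``w`` metres seen from ``d`` metres spans
``degrees(w / d)``.  With the default geometry (2.03 m wide screen at 2.0 m)
this yields a horizontal extent of 58.16 deg, matching the value quoted for
the simulator setup the package targets; the tangent convention would give
53.9 deg and is not used.

Two coordinate frames are handled:

* *screen degrees* — origin at the screen centre (eye level on the subject's
  mid-line), +x to the right, +y up;
* *pixels* — origin at the top-left corner, +x right, +y down (row-major),
  as delivered by the projector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import GeometryError

__all__ = ["ScreenGeometry", "angular_extent", "deg_per_px"]


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical screen, pixel resolution and viewing distance.

    Parameters
    ----------
    width_px, height_px : int
        Projector resolution in pixels.
    width_m, height_m : float
        Physical screen size in metres.
    distance_m : float
        Distance from the participant's head to the screen in metres.
    """

    width_px: int = 1400
    height_px: int = 1050
    width_m: float = 2.03
    height_m: float = 1.52
    distance_m: float = 2.0

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "width_m", "height_m", "distance_m"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be strictly positive, got {getattr(self, name)!r}")

    # -- angular extents ---------------------------------------------------

    def angular_extent(self) -> tuple[float, float]:
        """Horizontal and vertical extent of the screen in degrees."""
        h = math.degrees(self.width_m / self.distance_m)
        v = math.degrees(self.height_m / self.distance_m)
        return h, v

    def deg_per_px(self) -> tuple[float, float]:
        """Degrees per pixel along x and y."""
        h, v = self.angular_extent()
        return h / self.width_px, v / self.height_px

    # -- frame conversions -------------------------------------------------

    def deg_to_px(self, x_deg, y_deg):
        """Convert centre-origin screen degrees to top-left-origin pixels."""
        h, v = self.angular_extent()
        dx, dy = self.deg_per_px()
        px = (np.asarray(x_deg, dtype=float) + h / 2.0) / dx
        py = (v / 2.0 - np.asarray(y_deg, dtype=float)) / dy
        return px, py

    def px_to_deg(self, px, py):
        """Convert top-left-origin pixels to centre-origin screen degrees."""
        h, v = self.angular_extent()
        dx, dy = self.deg_per_px()
        x = np.asarray(px, dtype=float) * dx - h / 2.0
        y = v / 2.0 - np.asarray(py, dtype=float) * dy
        return x, y

    def contains_deg(self, x_deg, y_deg):
        """Boolean mask: does (x, y) in screen degrees lie on the screen?"""
        h, v = self.angular_extent()
        x = np.asarray(x_deg, dtype=float)
        y = np.asarray(y_deg, dtype=float)
        return (np.abs(x) <= h / 2.0) & (np.abs(y) <= v / 2.0)


def angular_extent(geom: ScreenGeometry) -> tuple[float, float]:
    """Angular extent (horizontal, vertical) of a screen in degrees."""
    return geom.angular_extent()


def deg_per_px(geom: ScreenGeometry) -> tuple[float, float]:
    """Angular size of one pixel (dx, dy) in degrees per pixel."""
    return geom.deg_per_px()
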