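"""Raster geometry: mapping between visual-field degrees and pixel coordinates.

The visual field is measured in degrees with ``x`` pointing right, ``y``
pointing up, and the fixation point at the origin.  A raster is a regular
pixel grid with pixel ``(0, 0)`` at the top-left corner and pixel *centers*
at half-integer pixel coordinates; the field of view is specified along the
raster diagonal, which fixes a single isotropic degrees-per-pixel scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["RasterSpec"]


@dataclass(frozen=True)
class RasterSpec:
    """Geometry of one eye's raster.

    Parameters
    ----------
    width_px, height_px
        Raster dimensions in pixels.
    fov_deg
        Field of view in visual degrees measured along the raster diagonal.
        The default matches a professional-grade binocular headset with a
        110 degree diagonal field of view.
    fixation
        Visual-field position (degrees) projected onto the raster center.
    """

    width_px: int = 1440
    height_px: int = 1600
    fov_deg: float = 110.0
    fixation: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (isinstance(self.width_px, (int, np.integer)) and self.width_px > 0):
            raise ValueError(f"width_px must be a positive integer, got {self.width_px!r}")
        if not (isinstance(self.height_px, (int, np.integer)) and self.height_px > 0):
            raise ValueError(f"height_px must be a positive integer, got {self.height_px!r}")
        if not (self.fov_deg > 0 and math.isfinite(self.fov_deg)):
            raise ValueError(f"fov_deg must be a positive real, got {self.fov_deg!r}")
        object.__setattr__(self, "fixation", (float(self.fixation[0]), float(self.fixation[1])))

    @property
    def shape(self) -> tuple[int, int]:
        """Array shape ``(height_px, width_px)``."""
        return (self.height_px, self.width_px)

    @property
    def deg_per_px(self) -> float:
        """Isotropic scale: visual degrees spanned by one pixel."""
        diag = math.hypot(self.width_px, self.height_px)
        return self.fov_deg / diag

    # -- conversions ------------------------------------------------------

    def px_to_deg(self, x_px, y_px):
        """Convert pixel coordinates (x right, y down) to visual degrees."""
        s = self.deg_per_px
        fx, fy = self.fixation
        x = (np.asarray(x_px, dtype=float) - self.width_px / 2.0) * s + fx
        y = (self.height_px / 2.0 - np.asarray(y_px, dtype=float)) * s + fy
        return x, y

    def deg_to_px(self, x_deg, y_deg):
        """Convert visual degrees to pixel coordinates (x right, y down)."""
        s = self.deg_per_px
        fx, fy = self.fixation
        x = (np.asarray(x_deg, dtype=float) - fx) / s + self.width_px / 2.0
        y = self.height_px / 2.0 - (np.asarray(y_deg, dtype=float) - fy) / s
        return x, y

    def pixel_center_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Visual-degree coordinates of every pixel center.

        Returns two ``(height_px, width_px)`` arrays ``(X_deg, Y_deg)``.
        """
        xs = np.arange(self.width_px) + 0.5
        ys = np.arange(self.height_px) + 0.5
        XP, YP = np.meshgrid(xs, ys)
        return self.px_to_deg(XP, YP)
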