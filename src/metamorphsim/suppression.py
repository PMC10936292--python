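"""Gaze-locked dark-spot suppression of the distorted retinal region.

A suppression spot is a black disk overlaid at a fixed *retinal* location:
it is specified as an offset from fixation and moves with the measured gaze,
so it always hides the same part of the visual field.  Its radius is a
fraction (``scale``) of the distortion extent radius; the study protocol
uses scales 0, 0.25, 0.90, and 1.20.  Because the extent radius covers
every kernel's support disk, any scale ≥ 1 covers all distorted pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .distortion import DistortionField, distortion_extent
from .raster import RasterSpec

__all__ = ["SuppressionSpot", "PROTOCOL_SCALES", "make_spot", "spot_mask", "apply_spot"]

#: Suppression levels of the study protocol, as fractions of the extent radius.
PROTOCOL_SCALES = (0.0, 0.25, 0.90, 1.20)


@dataclass(frozen=True)
class SuppressionSpot:
    """A dark disk at a fixed retinal position.

    ``retinal_center_deg`` is the offset from fixation; ``radius_deg`` equals
    ``scale`` times the extent radius of the field the spot was built from
    (``scale = 0`` gives the empty spot).
    """

    retinal_center_deg: tuple[float, float]
    radius_deg: float
    scale: float

    def __post_init__(self) -> None:
        if self.radius_deg < 0:
            raise ValueError(f"radius_deg must be >= 0, got {self.radius_deg!r}")
        if self.scale < 0:
            raise ValueError(f"scale must be >= 0, got {self.scale!r}")
        object.__setattr__(
            self, "retinal_center_deg",
            (float(self.retinal_center_deg[0]), float(self.retinal_center_deg[1])),
        )


def make_spot(field: DistortionField, scale: float) -> SuppressionSpot:
    """Build a spot covering ``scale`` times the distortion extent.

    The spot is centered on the extent centroid; its radius is
    ``scale × extent_radius``, so e.g. a single kernel with σ = 2° and α = 3
    at scale 1.2 yields a 7.2° radius.
    """
    if scale < 0:
        raise ValueError(f"scale must be >= 0, got {scale!r}")
    center, radius = distortion_extent(field)  # raises on empty field
    return SuppressionSpot((float(center[0]), float(center[1])), scale * radius, scale)


def spot_mask(spot: SuppressionSpot, gaze_deg, raster_spec: RasterSpec) -> np.ndarray:
    """Boolean raster mask of the spot for a given gaze direction.

    The disk is centered at ``gaze + retinal_center``; because the
    pixel↔degree map is affine, shifting gaze by Δ shifts the mask by exactly
    the pixel image of Δ.  A pixel is masked when its center lies within the
    disk (closed).
    """
    gx, gy = float(gaze_deg[0]), float(gaze_deg[1])
    if not (math.isfinite(gx) and math.isfinite(gy)):
        raise ValueError(f"gaze must be finite, got {gaze_deg!r}")
    X, Y = raster_spec.pixel_center_grid()
    cx = gx + spot.retinal_center_deg[0]
    cy = gy + spot.retinal_center_deg[1]
    if spot.radius_deg == 0.0:
        return np.zeros(raster_spec.shape, dtype=bool)
    return np.hypot(X - cx, Y - cy) <= spot.radius_deg


def apply_spot(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Black out the masked pixels; every other pixel is returned bit-exact."""
    image = np.asarray(image)
    if image.shape[:2] != mask.shape:
        raise ValueError(
            f"shape mismatch: image {image.shape[:2]} vs mask {mask.shape}"
        )
    out = image.copy()
    out[mask] = 0
    return out
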