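"""Simulated binocular observer: fill-in, perception metrics, 0–5 ratings.

The observer reduces a distorted percept to the two categorical ratings the
study protocol collects:

* perceived distortion of the Amsler grid, 0 (imperceptible) .. 5 (highest),
* illegibility of highlighted words, 0 (fully legible) .. 5 (illegible).

Perception is operationalized geometrically: metamorphopsia is by definition
the bending of straight lines, so the underlying metric is the mean residual
displacement magnitude over the task-relevant pixels (grid-line pixels, or
highlighted-word pixels), in units of the grid pitch.  Pixels hidden by the
suppression spot contribute nothing — the observer cannot see distortion
there — and the average is taken over all task pixels, which makes the
metric non-increasing as the spot grows and exactly zero once every
distorted pixel is covered.  Luminance loss can be folded in through a
configurable weight (default 0: geometric-only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from .distortion import (
    DistortionField,
    field_displacement,
    field_gain,
    residual_displacement,
)
from .raster import RasterSpec
from .stimuli import GridSpec, TemplateRanges, DEFAULT_RANGES, render_amsler

__all__ = [
    "ObserverThresholds",
    "SyntheticParticipant",
    "binocular_composite",
    "grid_distortion_metric",
    "legibility_metric",
    "to_score",
    "legibility_score",
    "participant_response",
    "reference_thresholds",
]


@dataclass(frozen=True)
class ObserverThresholds:
    """Reference metric values mapped to the top rating of each 0–5 scale."""

    grid_ref_metric: float
    legibility_ref_metric: float
    n_levels: int = 6

    def __post_init__(self) -> None:
        if not self.grid_ref_metric > 0:
            raise ValueError(f"grid_ref_metric must be > 0, got {self.grid_ref_metric!r}")
        if not self.legibility_ref_metric > 0:
            raise ValueError(
                f"legibility_ref_metric must be > 0, got {self.legibility_ref_metric!r}"
            )
        if self.n_levels != 6:
            raise ValueError("the rating scale is fixed at 6 levels (scores 0..5)")


@dataclass
class SyntheticParticipant:
    """Noisy stand-in for a human subject.

    ``score_noise_sd`` perturbs every rating (in score units, Gaussian);
    with probability ``lapse_rate`` a rating is replaced by a uniform draw
    from 0..5.  Zero noise and zero lapse give a deterministic function of
    the stimulus.  All randomness flows from ``seed``.
    """

    score_noise_sd: float = 0.0
    lapse_rate: float = 0.0
    seed: int = 0
    deadband: float = 0.02
    _rng: np.random.Generator = dc_field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.score_noise_sd < 0:
            raise ValueError(f"score_noise_sd must be >= 0, got {self.score_noise_sd!r}")
        if not (0.0 <= self.lapse_rate < 1.0):
            raise ValueError(f"lapse_rate must lie in [0, 1), got {self.lapse_rate!r}")
        self._rng = np.random.default_rng(self.seed)

    def perceive(self, metric: float, ref_metric: float) -> float:
        """The metric as the participant experiences it (noise in score units
        converted to metric units via ``ref_metric / 5``)."""
        if self.score_noise_sd == 0.0:
            return metric
        return max(0.0, metric + self._rng.normal(0.0, self.score_noise_sd * ref_metric / 5.0))

    def compare(self, new_metric: float, old_metric: float, ref_metric: float) -> int:
        """-1 if the new percept is better (less distorted), +1 if worse,
        0 within the perceptual indifference dead-band (relative 2%)."""
        new = self.perceive(new_metric, ref_metric)
        old = self.perceive(old_metric, ref_metric)
        band = self.deadband * max(old, 1e-12)
        if new < old - band:
            return -1
        if new > old + band:
            return 1
        return 0


def binocular_composite(affected_image: np.ndarray, healthy_image: np.ndarray,
                        suppression_mask: np.ndarray, mode: str = "binocular") -> np.ndarray:
    """Fuse the two eyes' images into the binocular percept.

    In ``binocular`` mode the healthy eye fills in the suppressed region:
    masked pixels come bit-exact from ``healthy_image``, the rest from
    ``affected_image`` (worst-case fusion: the distorted percept dominates
    outside the spot).  ``monocular_affected`` ignores the healthy image
    entirely — the contralateral display is off.
    """
    affected_image = np.asarray(affected_image)
    if mode not in ("binocular", "monocular_affected"):
        raise ValueError(f"unknown mode {mode!r}")
    if affected_image.shape[:2] != suppression_mask.shape:
        raise ValueError("image and mask shapes do not match")
    if mode == "monocular_affected":
        return affected_image.copy()
    healthy_image = np.asarray(healthy_image)
    if healthy_image.shape != affected_image.shape:
        raise ValueError("affected and healthy image shapes do not match")
    out = affected_image.copy()
    out[suppression_mask] = healthy_image[suppression_mask]
    return out


def _masked_mean_displacement(field: DistortionField, pixel_sel: np.ndarray,
                              suppression_mask, raster_spec: RasterSpec,
                              corrective: DistortionField | None = None,
                              luminance_weight: float = 0.0) -> float:
    """Mean residual |displacement| (degrees) over selected pixels.

    Suppressed pixels contribute 0; the mean is over all selected pixels.
    """
    n_total = int(pixel_sel.sum())
    if n_total == 0:
        return 0.0
    visible = pixel_sel if suppression_mask is None else (pixel_sel & ~suppression_mask)
    if not visible.any():
        return 0.0
    X, Y = raster_spec.pixel_center_grid()
    xs, ys = X[visible], Y[visible]
    if corrective is None:
        dx, dy = field_displacement(field, xs, ys)
    else:
        dx, dy = residual_displacement(field, corrective, xs, ys)
    total = float(np.hypot(dx, dy).sum())
    if luminance_weight != 0.0:
        total += luminance_weight * float((1.0 - field_gain(field, xs, ys)).sum())
    return total / n_total


def grid_distortion_metric(field: DistortionField, suppression_mask,
                           raster_spec: RasterSpec, grid_spec: GridSpec,
                           corrective: DistortionField | None = None,
                           luminance_weight: float = 0.0) -> float:
    """Perceived grid distortion in pitch units.

    Mean residual displacement magnitude over grid-line pixels, expressed as
    a fraction of the cell pitch; pixels covered by the suppression mask are
    invisible and contribute zero.  Zero for an empty field, and zero when
    the mask covers every distorted line pixel.
    """
    _, line_mask = render_amsler(grid_spec, raster_spec)
    mean_deg = _masked_mean_displacement(
        field, line_mask, suppression_mask, raster_spec, corrective, luminance_weight
    )
    return mean_deg / grid_spec.pitch_deg


def legibility_metric(field: DistortionField, suppression_mask, highlight_boxes,
                      raster_spec: RasterSpec, pitch_deg: float = 0.5,
                      corrective: DistortionField | None = None) -> float:
    """Residual-displacement metric restricted to highlighted-word pixels."""
    sel = np.zeros(raster_spec.shape, dtype=bool)
    H, W = raster_spec.shape
    for (x0, y0, x1, y1) in highlight_boxes:
        if x0 < 0 or y0 < 0 or x1 > W or y1 > H:
            raise ValueError(f"highlight box {(x0, y0, x1, y1)} exceeds raster bounds")
        sel[y0:y1, x0:x1] = True
    mean_deg = _masked_mean_displacement(field, sel, suppression_mask, raster_spec, corrective)
    return mean_deg / pitch_deg


def to_score(metric: float, ref_metric: float) -> int:
    """Map a non-negative metric to the 0–5 rating scale.

    ``round(5 · min(1, metric/ref_metric))`` with half-up rounding;
    monotone non-decreasing in the metric, 0 at metric 0, 5 at the
    reference and beyond.
    """
    if not ref_metric > 0:
        raise ValueError(f"ref_metric must be > 0, got {ref_metric!r}")
    x = 5.0 * min(1.0, metric / ref_metric)
    return int(math.floor(x + 0.5))


def legibility_score(field: DistortionField, suppression_mask, highlight_boxes,
                     raster_spec: RasterSpec, ref_metric: float,
                     pitch_deg: float = 0.5) -> int:
    """0 (fully legible) .. 5 (illegible) rating for the highlighted words."""
    m = legibility_metric(field, suppression_mask, highlight_boxes, raster_spec, pitch_deg)
    return to_score(m, ref_metric)


def participant_response(participant: SyntheticParticipant, true_score_metric: float,
                         ref_metric: float) -> int:
    """A (possibly noisy) 0–5 rating of a percept with the given metric."""
    rng = participant._rng
    if participant.lapse_rate > 0.0 and rng.random() < participant.lapse_rate:
        return int(rng.integers(0, 6))
    score = to_score(true_score_metric, ref_metric)
    if participant.score_noise_sd > 0.0:
        score = int(math.floor(score + rng.normal(0.0, participant.score_noise_sd) + 0.5))
    return int(np.clip(score, 0, 5))


def reference_thresholds(ranges: TemplateRanges = DEFAULT_RANGES,
                         grid_spec: GridSpec | None = None,
                         raster_spec: RasterSpec | None = None) -> ObserverThresholds:
    """Calibrate the score-5 reference metrics once, from the template ranges.

    The reference stimulus is the *strongest admissible template*: a single
    kernel at fixation with every amplitude at its interval extreme, viewed
    without suppression.  The grid reference is its grid-line metric; the
    legibility reference is its metric over a word-sized (5° × 1.5°) box
    centered on fixation.
    """
    grid_spec = grid_spec or GridSpec()
    raster_spec = raster_spec or RasterSpec(256, 256, 36.0)
    strongest = DistortionField((ranges.strongest_kernel(),))
    grid_ref = grid_distortion_metric(strongest, None, raster_spec, grid_spec)

    s = raster_spec.deg_per_px
    bw, bh = 5.0 / s, 1.5 / s
    cx, cy = raster_spec.width_px / 2.0, raster_spec.height_px / 2.0
    box = (int(cx - bw / 2), int(cy - bh / 2), int(cx + bw / 2), int(cy + bh / 2))
    leg_ref = legibility_metric(strongest, None, [box], raster_spec, grid_spec.pitch_deg)
    return ObserverThresholds(grid_ref_metric=grid_ref, legibility_ref_metric=leg_ref)
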