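"""Amsler-grid and reading-task stimuli, and random metamorphopsia templates.

The Amsler grid is the classical square grid with central fixation used to
screen for central-field distortion; here it is fully parameterized (cell
pitch, line width, line/background chromaticity, optional diagonals that
reinforce the fixation point for observers whose central vision is degraded).
The reading task renders lines of pronounceable pseudo-Latin nonsense words —
so a highlighted word can never be guessed from context — with a few words
highlighted for legibility scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from PIL import Image, ImageDraw, ImageFont

from .distortion import DistortionField, DistortionKernel
from .raster import RasterSpec

__all__ = [
    "GridSpec",
    "ReadingSpec",
    "TemplateRanges",
    "DEFAULT_RANGES",
    "render_amsler",
    "render_reading_task",
    "random_metamorphopsia",
    "severity_presets",
]


@dataclass(frozen=True)
class GridSpec:
    """Amsler-grid layout. The default is the classical 20°x20° grid with
    0.5° cells, black lines on white."""

    extent_deg: float = 20.0
    pitch_deg: float = 0.5
    line_width_px: int = 1
    line_chroma: tuple[int, int, int] = (0, 0, 0)
    background_chroma: tuple[int, int, int] = (255, 255, 255)
    diagonals: bool = True
    fixation_marker: bool = True

    def __post_init__(self) -> None:
        if not self.pitch_deg > 0:
            raise ValueError(f"pitch_deg must be > 0, got {self.pitch_deg!r}")
        if not self.extent_deg > 0:
            raise ValueError(f"extent_deg must be > 0, got {self.extent_deg!r}")
        if not (isinstance(self.line_width_px, (int, np.integer)) and self.line_width_px > 0):
            raise ValueError(f"line_width_px must be a positive integer, got {self.line_width_px!r}")
        if tuple(self.line_chroma) == tuple(self.background_chroma):
            raise ValueError("line_chroma and background_chroma must differ")


@dataclass(frozen=True)
class ReadingSpec:
    """Pseudo-Latin reading stimulus: word count, highlights, font size, seed."""

    n_words: int = 60
    n_highlighted: int = 3
    font_px: int = 28
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_words > 0:
            raise ValueError(f"n_words must be positive, got {self.n_words!r}")
        if not (0 < self.n_highlighted <= self.n_words):
            raise ValueError(
                f"n_highlighted must be in 1..n_words, got {self.n_highlighted!r}"
            )
        if not self.font_px > 0:
            raise ValueError(f"font_px must be positive, got {self.font_px!r}")


@dataclass(frozen=True)
class TemplateRanges:
    """Uniform sampling intervals for random metamorphopsia templates.

    Defaults describe moderate central-field distortions: one to three
    kernels of 1–2.5° sigma within 4° of fixation, luminance sensitivity
    loss 0.2–0.8, peak tangential rotation up to ±0.5 rad, and radial
    stretch −0.25 (squeeze) to +0.35 (stretch); supports truncated at 3σ.
    """

    n_kernels: tuple[int, int] = (1, 3)
    sigma_deg: tuple[float, float] = (1.0, 2.5)
    luminance_loss: tuple[float, float] = (0.2, 0.8)
    rotation_strength_rad: tuple[float, float] = (-0.5, 0.5)
    radial_stretch: tuple[float, float] = (-0.25, 0.35)
    center_eccentricity_deg: tuple[float, float] = (0.0, 4.0)
    boundary_alpha: float = 3.0

    def __post_init__(self) -> None:
        for name in ("n_kernels", "sigma_deg", "luminance_loss",
                     "rotation_strength_rad", "radial_stretch",
                     "center_eccentricity_deg"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} interval is empty: {lo!r} > {hi!r}")
        if self.n_kernels[0] < 1:
            raise ValueError("n_kernels lower bound must be >= 1")
        if self.sigma_deg[0] <= 0:
            raise ValueError("sigma_deg must be positive")
        if not (0 <= self.luminance_loss[0] and self.luminance_loss[1] <= 1):
            raise ValueError("luminance_loss interval must lie in [0, 1]")
        if self.radial_stretch[0] <= -1:
            raise ValueError("radial_stretch must stay > -1")
        if self.center_eccentricity_deg[0] < 0:
            raise ValueError("center_eccentricity_deg must be non-negative")
        if self.boundary_alpha < 1:
            raise ValueError("boundary_alpha must be >= 1")

    def strongest_kernel(self) -> DistortionKernel:
        """Kernel at fixation with every amplitude at its interval extreme.

        Used as the score-5 calibration reference: no admissible template can
        put more geometric distortion at one kernel than this.
        """
        rho = max(abs(self.rotation_strength_rad[0]), abs(self.rotation_strength_rad[1]))
        s = self.radial_stretch[1] if abs(self.radial_stretch[1]) >= abs(
            self.radial_stretch[0]) else self.radial_stretch[0]
        return DistortionKernel(
            (0.0, 0.0), self.sigma_deg[1], self.luminance_loss[1],
            rho, s, self.boundary_alpha,
        )


DEFAULT_RANGES = TemplateRanges()


# -- Amsler grid -----------------------------------------------------------


def _line_positions(extent: float, pitch: float) -> np.ndarray:
    """Grid-line coordinates: multiples of ``pitch`` within ±extent/2."""
    n = int(math.floor(extent / 2.0 / pitch + 1e-9))
    return np.arange(-n, n + 1) * pitch


def render_amsler(grid_spec: GridSpec, raster_spec: RasterSpec):
    """Rasterize an Amsler grid centered on fixation.

    Returns ``(image, line_mask)`` where ``image`` is ``(H, W, 3)`` uint8 and
    ``line_mask`` is boolean, True on grid-line (and diagonal) pixels.  A
    pixel belongs to a line when its center lies within half the line width
    of the line's geometric locus.  Deterministic.
    """
    X, Y = raster_spec.pixel_center_grid()
    half_ext = grid_spec.extent_deg / 2.0
    half_w = grid_spec.line_width_px * raster_spec.deg_per_px / 2.0
    pos = _line_positions(grid_spec.extent_deg, grid_spec.pitch_deg)

    in_grid = (np.abs(X) <= half_ext + half_w) & (np.abs(Y) <= half_ext + half_w)

    def _near_line(coord):
        # distance to nearest grid-line coordinate
        d = np.min(np.abs(coord[..., None] - pos[None, None, :]), axis=-1)
        return d <= half_w

    mask = in_grid & (_near_line(X) | _near_line(Y))
    if grid_spec.diagonals:
        # diagonals y = ±x through fixation; perpendicular distance
        d1 = np.abs(X - Y) / math.sqrt(2.0)
        d2 = np.abs(X + Y) / math.sqrt(2.0)
        mask |= in_grid & ((d1 <= half_w) | (d2 <= half_w))
    if grid_spec.fixation_marker:
        mask |= np.hypot(X, Y) <= 2.5 * half_w

    image = np.empty(raster_spec.shape + (3,), dtype=np.uint8)
    image[...] = np.asarray(grid_spec.background_chroma, dtype=np.uint8)
    image[mask] = np.asarray(grid_spec.line_chroma, dtype=np.uint8)
    return image, mask


# -- reading task ----------------------------------------------------------

_ONSETS = ["b", "c", "d", "f", "g", "l", "m", "n", "p", "r", "s", "t", "v"]
_VOWELS = ["a", "e", "i", "o", "u"]
_CODAS = ["", "", "", "m", "n", "r", "s", "t"]


def _pseudo_latin_word(rng: np.random.Generator) -> str:
    """One pronounceable nonsense word of 2–4 CV/CVC syllables."""
    n_syll = int(rng.integers(2, 5))
    parts = []
    for _ in range(n_syll):
        parts.append(rng.choice(_ONSETS) + rng.choice(_VOWELS) + rng.choice(_CODAS))
    return "".join(parts)


def render_reading_task(reading_spec: ReadingSpec, raster_spec: RasterSpec):
    """Render a pseudo-Latin reading stimulus.

    Returns ``(image, highlight_boxes)``: an ``(H, W, 3)`` uint8 image of
    black text on white with ``n_highlighted`` randomly chosen words drawn
    over a translucent yellow box, and the list of those boxes as pixel
    rectangles ``(x0, y0, x1, y1)`` (half-open).  Identical seeds produce
    byte-identical output.

    Raises
    ------
    ValueError
        If the words do not fit on the raster at the requested font size.
    """
    rng = np.random.default_rng(reading_spec.seed)
    words = [_pseudo_latin_word(rng) for _ in range(reading_spec.n_words)]
    highlighted = set(
        rng.choice(reading_spec.n_words, size=reading_spec.n_highlighted, replace=False).tolist()
    )

    W, H = raster_spec.width_px, raster_spec.height_px
    img = Image.new("RGB", (W, H), (255, 255, 255))
    draw = ImageDraw.Draw(img)
    font = ImageFont.load_default(size=reading_spec.font_px)

    margin = max(4, reading_spec.font_px // 2)
    space = draw.textlength(" ", font=font)
    line_h = int(reading_spec.font_px * 1.5)
    x, y = margin, margin
    boxes = []
    for i, word in enumerate(words):
        w = draw.textlength(word, font=font)
        if x + w > W - margin:
            x = margin
            y += line_h
        if y + line_h > H - margin or w > W - 2 * margin:
            raise ValueError(
                f"text overflow: {reading_spec.n_words} words at font_px="
                f"{reading_spec.font_px} do not fit a {W}x{H} raster"
            )
        if i in highlighted:
            box = (int(x) - 2, int(y) - 2, int(math.ceil(x + w)) + 2, y + line_h - 2)
            draw.rectangle([box[0], box[1], box[2] - 1, box[3] - 1], fill=(255, 240, 150))
            boxes.append(box)
        draw.text((x, y), word, fill=(0, 0, 0), font=font)
        x += w + space
    return np.asarray(img), boxes


# -- random templates ------------------------------------------------------


def random_metamorphopsia(seed: int, ranges: TemplateRanges = DEFAULT_RANGES,
                          eye: str = "left") -> DistortionField:
    """Draw a random metamorphopsia template, reproducibly.

    The kernel count is uniform on its integer interval; each kernel draws
    every parameter uniformly from its interval, with the center placed at a
    uniform eccentricity and uniform polar angle about fixation.
    """
    rng = np.random.default_rng(seed)
    lo, hi = ranges.n_kernels
    n = int(rng.integers(lo, hi + 1))
    kernels = []
    for _ in range(n):
        ecc = rng.uniform(*ranges.center_eccentricity_deg)
        angle = rng.uniform(0.0, 2.0 * math.pi)
        kernels.append(DistortionKernel(
            center=(ecc * math.cos(angle), ecc * math.sin(angle)),
            sigma_deg=float(rng.uniform(*ranges.sigma_deg)),
            luminance_loss=float(rng.uniform(*ranges.luminance_loss)),
            rotation_strength_rad=float(rng.uniform(*ranges.rotation_strength_rad)),
            radial_stretch=float(rng.uniform(*ranges.radial_stretch)),
            boundary_alpha=ranges.boundary_alpha,
        ))
    return DistortionField(tuple(kernels), eye=eye)


def severity_presets(base: TemplateRanges = DEFAULT_RANGES, n: int = 6) -> list[TemplateRanges]:
    """Evenly spaced severity levels: amplitude intervals scaled by m = 1/n..1.

    Only the perceptual amplitudes (luminance loss, rotation, stretch) are
    scaled; geometry (sigma, eccentricity, boundary) is shared across levels.
    """
    presets = []
    for i in range(1, n + 1):
        m = i / n
        presets.append(TemplateRanges(
            n_kernels=base.n_kernels,
            sigma_deg=base.sigma_deg,
            luminance_loss=(base.luminance_loss[0] * m, base.luminance_loss[1] * m),
            rotation_strength_rad=(base.rotation_strength_rad[0] * m,
                                   base.rotation_strength_rad[1] * m),
            radial_stretch=(base.radial_stretch[0] * m, base.radial_stretch[1] * m),
            center_eccentricity_deg=base.center_eccentricity_deg,
            boundary_alpha=base.boundary_alpha,
        ))
    return presets
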