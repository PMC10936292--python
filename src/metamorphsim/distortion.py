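"""Parametric metamorphopsia fields and their rasterization.

Metamorphopsia — the perceived bending of straight lines caused by macular
pathology — is modeled as a mixture of circular distortion kernels.  Each
kernel is a truncated Gaussian profile over the visual field that carries
three perceptual amplitudes sharing one (center, sigma, boundary) geometry:

* ``luminance_loss`` (λ): multiplicative loss of luminance sensitivity,
* ``rotation_strength_rad`` (ρ): peak tangential rotation of the field,
* ``radial_stretch`` (s): signed radial stretch (>0) or squeeze (<0).

Writing ``v = p − center``, ``r = |v|`` and the truncated Gaussian profile
``g(r) = exp(−r²/2σ²)·T(r)`` (``T`` is a smoothstep from 1 to 0 over
``[(α−0.5)σ, ασ]`` so every contribution vanishes smoothly at the support
boundary ``r = ασ``), a kernel maps the backward sample point of ``p`` to

    center + Rot(θ(r)) · v · (1 + s·g(r)),
    θ(r) = ρ · (r/σ) · exp(1/2 − r²/2σ²) · T(r),

i.e. rotate-then-scale; the tangential angle grows from zero at the center,
peaks with value ρ at ``r = σ``, and decays to zero at the boundary.
Kernel displacements add across the mixture; luminance gains multiply.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy.ndimage import map_coordinates
from scipy.optimize import minimize

from .raster import RasterSpec

__all__ = [
    "DistortionKernel",
    "DistortionField",
    "make_kernel",
    "kernel_weight",
    "displacement_at",
    "render_maps",
    "warp_image",
    "invert_displacement",
    "fit_corrective_field",
    "distortion_extent",
    "field_displacement",
    "residual_displacement",
    "load_template",
    "save_template",
]

_KERNEL_FIELDS = (
    "center",
    "sigma_deg",
    "luminance_loss",
    "rotation_strength_rad",
    "radial_stretch",
    "boundary_alpha",
)


@dataclass(frozen=True)
class DistortionKernel:
    """One circular metamorphopsia unit (see module docstring for the math)."""

    center: tuple[float, float]
    sigma_deg: float
    luminance_loss: float = 0.0
    rotation_strength_rad: float = 0.0
    radial_stretch: float = 0.0
    boundary_alpha: float = 3.0

    def __post_init__(self) -> None:
        cx, cy = float(self.center[0]), float(self.center[1])
        if not (math.isfinite(cx) and math.isfinite(cy)):
            raise ValueError(f"center must be finite, got {self.center!r}")
        object.__setattr__(self, "center", (cx, cy))
        if not (self.sigma_deg > 0 and math.isfinite(self.sigma_deg)):
            raise ValueError(f"sigma_deg must be > 0, got {self.sigma_deg!r}")
        if not (0.0 <= self.luminance_loss <= 1.0):
            raise ValueError(
                f"luminance_loss must lie in [0, 1], got {self.luminance_loss!r}"
            )
        if not math.isfinite(self.rotation_strength_rad):
            raise ValueError(
                f"rotation_strength_rad must be finite, got {self.rotation_strength_rad!r}"
            )
        if not (self.radial_stretch > -1.0 and math.isfinite(self.radial_stretch)):
            raise ValueError(
                f"radial_stretch must be > -1, got {self.radial_stretch!r}"
            )
        if not (self.boundary_alpha >= 1.0):
            raise ValueError(
                f"boundary_alpha must be >= 1, got {self.boundary_alpha!r}"
            )

    @property
    def support_radius_deg(self) -> float:
        """Radius ``α·σ`` of the closed support disk about ``center``."""
        return self.boundary_alpha * self.sigma_deg


@dataclass(frozen=True)
class DistortionField:
    """Per-eye mixture of distortion kernels; an empty list is the identity."""

    kernels: tuple[DistortionKernel, ...] = ()
    eye: str = "left"

    def __post_init__(self) -> None:
        object.__setattr__(self, "kernels", tuple(self.kernels))
        if self.eye not in ("left", "right"):
            raise ValueError(f"eye must be 'left' or 'right', got {self.eye!r}")

    def __len__(self) -> int:
        return len(self.kernels)


def make_kernel(
    center,
    sigma_deg,
    luminance_loss=0.0,
    rotation_strength_rad=0.0,
    radial_stretch=0.0,
    boundary_alpha=3.0,
) -> DistortionKernel:
    """Construct and validate a :class:`DistortionKernel` (pure)."""
    return DistortionKernel(
        center=(center[0], center[1]),
        sigma_deg=float(sigma_deg),
        luminance_loss=float(luminance_loss),
        rotation_strength_rad=float(rotation_strength_rad),
        radial_stretch=float(radial_stretch),
        boundary_alpha=float(boundary_alpha),
    )


def _truncation(r, sigma, alpha):
    """Smoothstep from 1 to 0 over ``[(α−0.5)σ, ασ]``; exactly 0 beyond."""
    t = np.clip((np.asarray(r, dtype=float) - (alpha - 0.5) * sigma) / (0.5 * sigma), 0.0, 1.0)
    return 1.0 - t * t * (3.0 - 2.0 * t)


def _profile(r, sigma, alpha):
    """Truncated Gaussian profile ``g(r) = exp(−r²/2σ²)·T(r)``."""
    r = np.asarray(r, dtype=float)
    return np.exp(-(r * r) / (2.0 * sigma * sigma)) * _truncation(r, sigma, alpha)


def kernel_weight(kernel: DistortionKernel, point_deg) -> float:
    """Truncated Gaussian weight of ``kernel`` at a visual-field point.

    Equals 1 at the center, ``exp(−1/2)`` at one sigma (for α well beyond 1),
    and exactly 0 at and outside the support boundary ``r = α·σ``.
    """
    p = np.asarray(point_deg, dtype=float)
    r = math.hypot(p[0] - kernel.center[0], p[1] - kernel.center[1])
    return float(_profile(r, kernel.sigma_deg, kernel.boundary_alpha))


def _kernel_offsets(kernel: DistortionKernel, X, Y):
    """Backward-sampling offset (degrees) of one kernel at coordinate arrays."""
    vx = X - kernel.center[0]
    vy = Y - kernel.center[1]
    r = np.hypot(vx, vy)
    sigma = kernel.sigma_deg
    T = _truncation(r, sigma, kernel.boundary_alpha)
    q = (r * r) / (2.0 * sigma * sigma)
    g = np.exp(-q) * T
    theta = kernel.rotation_strength_rad * (r / sigma) * np.exp(0.5 - q) * T
    scale = 1.0 + kernel.radial_stretch * g
    c, s = np.cos(theta), np.sin(theta)
    # rotate-then-scale: Rot(theta) @ v, then radial scaling
    sx = (c * vx - s * vy) * scale
    sy = (s * vx + c * vy) * scale
    return sx - vx, sy - vy


def field_displacement(field: DistortionField, X, Y):
    """Summed backward-sampling displacement (degrees) at coordinate arrays.

    ``X``/``Y`` may be scalars or arrays of any broadcastable shape.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    dx = np.zeros(np.broadcast(X, Y).shape, dtype=float)
    dy = np.zeros_like(dx)
    for kernel in field.kernels:
        ox, oy = _kernel_offsets(kernel, X, Y)
        dx += ox
        dy += oy
    return dx, dy


def displacement_at(field: DistortionField, point_deg) -> np.ndarray:
    """Backward-sampling displacement (degrees) of ``field`` at one point."""
    p = np.asarray(point_deg, dtype=float)
    dx, dy = field_displacement(field, p[0], p[1])
    return np.array([float(dx), float(dy)])


def field_gain(field: DistortionField, X, Y):
    """Multiplicative luminance gain ``∏ₖ (1 − λₖ·wₖ)`` at coordinate arrays."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    gain = np.ones(np.broadcast(X, Y).shape, dtype=float)
    for kernel in field.kernels:
        if kernel.luminance_loss == 0.0:
            continue
        r = np.hypot(X - kernel.center[0], Y - kernel.center[1])
        w = _profile(r, kernel.sigma_deg, kernel.boundary_alpha)
        gain *= 1.0 - kernel.luminance_loss * w
    return gain


def render_maps(field: DistortionField, raster_spec: RasterSpec):
    """Rasterize a field to per-pixel displacement (pixels) and luminance gain.

    Returns
    -------
    displacement_map : ``(H, W, 2)`` float array
        Backward-sampling offsets in *pixel* coordinates ``(dx_px, dy_px)``
        with x right and y down.
    luminance_map : ``(H, W)`` float array in [0, 1]
        Multiplicative gain, 1 outside all kernel supports.
    """
    X, Y = raster_spec.pixel_center_grid()
    dx_deg, dy_deg = field_displacement(field, X, Y)
    s = raster_spec.deg_per_px
    disp = np.empty(raster_spec.shape + (2,), dtype=float)
    disp[..., 0] = dx_deg / s
    disp[..., 1] = -dy_deg / s  # raster y runs downward
    return disp, field_gain(field, X, Y)


def warp_image(image: np.ndarray, displacement_map: np.ndarray, luminance_map: np.ndarray) -> np.ndarray:
    """Warp an image by backward mapping and apply the luminance gain.

    Output pixel ``p`` bilinearly samples the input at ``p + displacement(p)``
    (edge-clamped) and is multiplied by ``luminance_map[p]``.  Integer images
    are rounded back to their dtype; where displacement is zero and gain is
    one the result is bit-exact.
    """
    image = np.asarray(image)
    if image.shape[:2] != displacement_map.shape[:2] or image.shape[:2] != luminance_map.shape[:2]:
        raise ValueError(
            f"shape mismatch: image {image.shape[:2]}, displacement "
            f"{displacement_map.shape[:2]}, luminance {luminance_map.shape[:2]}"
        )
    H, W = image.shape[:2]
    jj, ii = np.meshgrid(np.arange(H, dtype=float), np.arange(W, dtype=float), indexing="ij")
    cols = ii + displacement_map[..., 0]
    rows = jj + displacement_map[..., 1]
    coords = np.stack([rows, cols])

    def _warp_channel(ch):
        out = map_coordinates(ch.astype(float), coords, order=1, mode="nearest")
        return out * luminance_map

    if image.ndim == 2:
        out = _warp_channel(image)
    else:
        out = np.stack([_warp_channel(image[..., c]) for c in range(image.shape[2])], axis=-1)

    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        out = np.clip(np.rint(out), info.min, info.max).astype(image.dtype)
    else:
        out = out.astype(image.dtype, copy=False)
    return out


def _sample_map(displacement_map: np.ndarray, cols, rows) -> tuple[np.ndarray, np.ndarray]:
    coords = np.stack([rows, cols])
    dx = map_coordinates(displacement_map[..., 0], coords, order=1, mode="nearest")
    dy = map_coordinates(displacement_map[..., 1], coords, order=1, mode="nearest")
    return dx, dy


def invert_displacement(displacement_map: np.ndarray, tol: float = 0.05,
                        max_iter: int = 200, relaxation: float = 0.7) -> np.ndarray:
    """Dense inverse of a backward displacement map by fixed-point iteration.

    Solves ``d(p + d⁻¹(p)) + d⁻¹(p) = 0`` per pixel with the under-relaxed
    update ``d⁻¹ ← d⁻¹ − ω·(d(p + d⁻¹) + d⁻¹)`` (bilinear sampling of ``d``;
    ``ω = 1`` is the plain iteration ``d⁻¹ ← −d(p + d⁻¹)``).  The default
    ``ω = 0.7`` keeps the iteration contractive where strong overlapping
    kernels push the map's Jacobian near unity.  Stops when the worst
    per-pixel residual ``max |d(p + d⁻¹(p)) + d⁻¹(p)|`` falls below ``tol``
    pixels.

    Raises
    ------
    RuntimeError
        If the residual has not dropped below ``tol`` after ``max_iter``
        sweeps; the message reports the worst residual reached.
    """
    if not tol > 0:
        raise ValueError(f"tol must be > 0, got {tol!r}")
    H, W = displacement_map.shape[:2]
    jj, ii = np.meshgrid(np.arange(H, dtype=float), np.arange(W, dtype=float), indexing="ij")
    inv = np.zeros_like(displacement_map)
    worst = np.inf
    for _ in range(max_iter):
        dx, dy = _sample_map(displacement_map, ii + inv[..., 0], jj + inv[..., 1])
        residual = np.stack([dx, dy], axis=-1) + inv
        worst = float(np.hypot(residual[..., 0], residual[..., 1]).max())
        if worst < tol:
            return inv
        inv = inv - relaxation * residual
    raise RuntimeError(
        f"displacement inversion did not converge in {max_iter} iterations "
        f"(worst residual {worst:.4g} px)"
    )


def residual_displacement(field: DistortionField, corrective: DistortionField, X, Y):
    """Residual displacement (degrees) of correct-then-distort composition.

    With backward warps applied in sequence (corrective ``C`` viewed last),
    the percept at point ``p`` samples the scene at
    ``p + d_C(p) + d_F(p + d_C(p))``; this returns that net offset.
    A perfect corrective field drives it to zero everywhere.
    """
    cx, cy = field_displacement(corrective, X, Y)
    fx, fy = field_displacement(field, np.asarray(X, float) + cx, np.asarray(Y, float) + cy)
    return cx + fx, cy + fy


def _corrective_params(field: DistortionField, n_kernels: int) -> tuple[np.ndarray, list[float]]:
    """Initial parameter vector: negated amplitudes of the leading kernels.

    Kernels beyond those of ``field`` are seeded as narrow (σ/√2) companions
    of the last kernel with small amplitudes — the leading correction to a
    radial stretch is a squared-Gaussian term, which lives at σ/√2.
    """
    params, alphas = [], []
    kernels = list(field.kernels)
    for i in range(n_kernels):
        if i < len(kernels):
            k = kernels[i]
            params.extend(
                [k.center[0], k.center[1], k.sigma_deg, -k.rotation_strength_rad,
                 -k.radial_stretch / (1.0 + k.radial_stretch)]
            )
        else:
            k = kernels[-1] if kernels else DistortionKernel((0.0, 0.0), 1.0)
            params.extend(
                [k.center[0], k.center[1], k.sigma_deg / math.sqrt(2.0), 0.0, 0.05]
            )
        alphas.append(k.boundary_alpha)
    return np.asarray(params, dtype=float), alphas


def _params_to_field(params: np.ndarray, alphas: list[float], eye: str) -> DistortionField:
    kernels = []
    for i, alpha in enumerate(alphas):
        cx, cy, sigma, rho, s = params[5 * i : 5 * i + 5]
        sigma = max(abs(sigma), 1e-3)
        s = max(s, -0.95)
        kernels.append(
            DistortionKernel((cx, cy), sigma, 0.0, rho, s, alpha)
        )
    return DistortionField(tuple(kernels), eye=eye)


@dataclass(frozen=True)
class CorrectiveFit:
    """A fitted corrective field with its mean-squared residual objective."""

    field: DistortionField
    objective: float
    converged: bool
    n_evaluations: int


def fit_corrective_field(
    field: DistortionField,
    raster_spec: RasterSpec,
    n_kernels: int = 1,
    budget: int = 2000,
    sample_stride: int = 4,
) -> CorrectiveFit:
    """Fit a parametric corrective field that cancels ``field``.

    Minimizes the mean squared residual displacement of the composition
    (warp by corrective) ∘ (warp by ``field``) over a strided sample of the
    raster, by Nelder–Mead simplex search seeded from the negated amplitudes
    of ``field``'s kernels.  Purely-geometric corrective kernels are fitted
    (luminance loss cannot be undone by adding light and is left at zero).
    The returned objective never exceeds that of the all-zero corrective
    field; the search never raises on budget exhaustion.
    """
    if n_kernels < 1:
        raise ValueError(f"n_kernels must be >= 1, got {n_kernels!r}")
    X, Y = raster_spec.pixel_center_grid()
    X = X[::sample_stride, ::sample_stride].ravel()
    Y = Y[::sample_stride, ::sample_stride].ravel()

    empty = DistortionField((), eye=field.eye)

    def objective(params_or_field) -> float:
        C = params_or_field
        rx, ry = residual_displacement(field, C, X, Y)
        return float(np.mean(rx * rx + ry * ry))

    zero_obj = objective(empty)
    if len(field) == 0 or zero_obj == 0.0:
        return CorrectiveFit(empty, 0.0, True, 1)

    x0, alphas = _corrective_params(field, n_kernels)

    def f(params):
        return objective(_params_to_field(params, alphas, field.eye))

    # Nelder-Mead with restarts: the simplex can collapse prematurely, so
    # re-seed it at the incumbent until the budget is spent or it stalls.
    x, best_obj, nfev, success = x0, math.inf, 0, False
    while nfev < budget:
        res = minimize(
            f,
            x,
            method="Nelder-Mead",
            options={"maxfev": budget - nfev, "xatol": 1e-7, "fatol": 1e-14},
        )
        nfev += int(res.nfev)
        success = bool(res.success)
        if res.fun >= best_obj * (1.0 - 1e-3):
            best_obj = min(best_obj, float(res.fun))
            x = res.x if res.fun < best_obj else x
            break
        best_obj, x = float(res.fun), res.x
    best_field = _params_to_field(x, alphas, field.eye)
    best_obj = objective(best_field)
    if best_obj > zero_obj:
        best_field, best_obj = empty, zero_obj
    return CorrectiveFit(best_field, best_obj, success, nfev)


def distortion_extent(field: DistortionField) -> tuple[np.ndarray, float]:
    """Center and covering radius (degrees) of a field's distorted region.

    The center is the amplitude-weighted mean of kernel centers, with each
    kernel weighted by ``max(λ, |ρ|, |s|)`` (uniform weights if all kernels
    have zero amplitude); the radius is the smallest value such that the disk
    covers every kernel's support disk.
    """
    if len(field) == 0:
        raise ValueError("distortion_extent requires a non-empty field")
    centers = np.array([k.center for k in field.kernels], dtype=float)
    weights = np.array(
        [max(k.luminance_loss, abs(k.rotation_strength_rad), abs(k.radial_stretch))
         for k in field.kernels]
    )
    if weights.sum() == 0.0:
        weights = np.ones(len(field))
    center = (centers * weights[:, None]).sum(axis=0) / weights.sum()
    radius = max(
        float(np.hypot(*(np.asarray(k.center) - center)) + k.support_radius_deg)
        for k in field.kernels
    )
    return center, radius


# -- template serialization -----------------------------------------------


def _field_to_dict(field: DistortionField) -> dict:
    return {
        "eye": field.eye,
        "kernels": [
            {
                "center": [k.center[0], k.center[1]],
                "sigma_deg": k.sigma_deg,
                "luminance_loss": k.luminance_loss,
                "rotation_strength_rad": k.rotation_strength_rad,
                "radial_stretch": k.radial_stretch,
                "boundary_alpha": k.boundary_alpha,
            }
            for k in field.kernels
        ],
    }


def _field_from_dict(data: dict) -> DistortionField:
    kernels = []
    for entry in data.get("kernels", []):
        unknown = set(entry) - set(_KERNEL_FIELDS)
        if unknown:
            raise ValueError(f"unknown kernel fields: {sorted(unknown)}")
        kernels.append(DistortionKernel(center=tuple(entry["center"]), **{
            k: entry[k] for k in _KERNEL_FIELDS if k != "center" and k in entry
        }))
    return DistortionField(tuple(kernels), eye=data.get("eye", "left"))


def save_template(field: DistortionField, path) -> None:
    """Serialize a field to YAML (or JSON when the path ends in .json)."""
    data = _field_to_dict(field)
    path = str(path)
    with open(path, "w") as fh:
        if path.endswith(".json"):
            json.dump(data, fh, indent=2)
        else:
            yaml.safe_dump(data, fh, sort_keys=False)


def load_template(path) -> DistortionField:
    """Load a distortion template saved by :func:`save_template`."""
    path = str(path)
    with open(path) as fh:
        data = json.load(fh) if path.endswith(".json") else yaml.safe_load(fh)
    return _field_from_dict(data)
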