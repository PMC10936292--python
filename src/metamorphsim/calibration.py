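"""Interactive calibration procedures run against a synthetic participant.

Three procedures, each a human-in-the-loop optimization in which the only
oracle is the participant's report:

* :func:`reconstruct_contralateral` — the classical perceptual-deficit
  reconstruction: the subject recreates, in the contralateral eye, the
  distortion they perceive in the affected eye (coordinate descent on the
  kernel parameters, guided by remembered-similarity comparisons).
* :func:`corrective_assessment` — the direct approach: a corrective field is
  adjusted on the affected eye itself until the subject reports the
  distortion has disappeared (the contralateral display stays off).
* :func:`macular_hole_procedure` — the stepwise examiner protocol for a
  single focal distortion: localize the center with a movable dot, grow a
  circle until it covers the distorted area, rotate tangentially (clockwise
  first, reversing on a "worse" report), then contort radially (inward
  first, reversing on a "worse" report), refining until the subject reports
  the distortion imperceptible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
from scipy.optimize import minimize

from .distortion import (
    DistortionField,
    DistortionKernel,
    field_displacement,
    field_gain,
    fit_corrective_field,
    residual_displacement,
)
from .observer import SyntheticParticipant, grid_distortion_metric, to_score, reference_thresholds
from .raster import RasterSpec
from .stimuli import GridSpec, TemplateRanges, DEFAULT_RANGES, random_metamorphopsia

__all__ = [
    "CalibrationResult",
    "StepSizes",
    "reconstruct_contralateral",
    "corrective_assessment",
    "macular_hole_procedure",
]

# Evaluation geometry shared by the procedures: a small raster is plenty to
# resolve the default template ranges and keeps each participant query cheap.
_RASTER = RasterSpec(192, 192, 36.0)
_GRID = GridSpec()


@dataclass(frozen=True)
class StepSizes:
    """Examiner step sizes (degrees / radians / dimensionless stretch)."""

    center_deg: float = 0.25
    radius_deg: float = 0.25
    rotation_rad: float = 0.05
    contortion: float = 0.05


@dataclass
class CalibrationResult:
    """Outcome of one calibration loop."""

    fitted_field: DistortionField
    objective_trace: list[float]
    converged: bool
    n_queries: int
    final_score: int | None = None
    log: list[str] = dc_field(default_factory=list)


def _lattice(half_extent_deg: float = 12.0, step_deg: float = 0.3):
    ax = np.arange(-half_extent_deg, half_extent_deg + 1e-9, step_deg)
    X, Y = np.meshgrid(ax, ax)
    return X.ravel(), Y.ravel()


def _dissimilarity(candidate: DistortionField, target_maps, X, Y,
                   luminance_weight: float = 1.0) -> float:
    """RMS difference between candidate and remembered-target percepts."""
    tdx, tdy, tgain = target_maps
    dx, dy = field_displacement(candidate, X, Y)
    geo = math.sqrt(float(np.mean((dx - tdx) ** 2 + (dy - tdy) ** 2)))
    lum = math.sqrt(float(np.mean((field_gain(candidate, X, Y) - tgain) ** 2)))
    return geo + luminance_weight * lum


def _mid(interval) -> float:
    return 0.5 * (interval[0] + interval[1])


def reconstruct_contralateral(target_field: DistortionField,
                              participant: SyntheticParticipant,
                              ranges: TemplateRanges = DEFAULT_RANGES,
                              budget: int = 600) -> CalibrationResult:
    """Recreate a remembered distortion in the contralateral eye.

    Coordinate descent over each candidate kernel's (center, sigma, lambda,
    rho, s), starting from mid-range defaults.  At every step the participant
    compares the candidate's rendered distortion against the remembered
    target (similarity report with memory noise); only reported improvements
    are accepted.  Returns the best parameters found; ``converged`` is False
    when the query budget ran out first.
    """
    X, Y = _lattice()
    tdx, tdy = field_displacement(target_field, X, Y)
    target_maps = (tdx, tdy, field_gain(target_field, X, Y))
    thresholds = reference_thresholds(ranges, _GRID, _RASTER)
    ref = thresholds.grid_ref_metric

    n_kernels = max(1, len(target_field))
    params = []
    for _ in range(n_kernels):
        params.extend([0.0, 0.0, _mid(ranges.sigma_deg), _mid(ranges.luminance_loss),
                       _mid(ranges.rotation_strength_rad), _mid(ranges.radial_stretch)])
    params = np.asarray(params, dtype=float)

    lo = np.tile([-20.0, -20.0, max(ranges.sigma_deg[0], 1e-2), 0.0,
                  ranges.rotation_strength_rad[0] - 0.5, max(ranges.radial_stretch[0] - 0.3, -0.9)],
                 n_kernels)
    hi = np.tile([20.0, 20.0, ranges.sigma_deg[1] * 2.0, 1.0,
                  ranges.rotation_strength_rad[1] + 0.5, ranges.radial_stretch[1] + 0.3],
                 n_kernels)

    def make_field(p) -> DistortionField:
        kernels = []
        for i in range(n_kernels):
            cx, cy, sig, lam, rho, s = p[6 * i : 6 * i + 6]
            kernels.append(DistortionKernel((cx, cy), sig, lam, rho, s, ranges.boundary_alpha))
        return DistortionField(tuple(kernels), eye=target_field.eye)

    # Initial center steps are large: a 2 degree jump changes the percept
    # overlap enough to clear the participant's 2% indifference dead-band.
    steps = np.tile([2.0, 2.0, 0.4, 0.15, 0.15, 0.08], n_kernels)
    min_steps = steps / 64.0

    current = _dissimilarity(make_field(params), target_maps, X, Y)
    trace = [current]
    n_queries = 0
    converged = True
    while converged and np.any(steps > min_steps):
        improved_any = False
        for j in range(params.size):
            for direction in (+1.0, -1.0):
                stepped = False
                while n_queries < budget:
                    trial = params.copy()
                    trial[j] = float(np.clip(trial[j] + direction * steps[j], lo[j], hi[j]))
                    if trial[j] == params[j]:
                        break
                    cand = _dissimilarity(make_field(trial), target_maps, X, Y)
                    n_queries += 1
                    if participant.compare(cand, current, ref) < 0:
                        params, current = trial, cand
                        trace.append(current)
                        improved_any = stepped = True
                    else:
                        break
                if stepped or n_queries >= budget:
                    break  # a successful direction ends this coordinate's turn
            if n_queries >= budget:
                converged = False
                break
        if not improved_any:
            steps /= 2.0
    return CalibrationResult(make_field(params), trace, converged, n_queries)


def _corrective_metric(affected: DistortionField, corrective: DistortionField,
                       line_pixels, pitch_deg: float) -> float:
    """Grid metric of the corrected percept over precomputed line pixels."""
    xs, ys, n_total = line_pixels
    rx, ry = residual_displacement(affected, corrective, xs, ys)
    return float(np.hypot(rx, ry).sum()) / n_total / pitch_deg


def _line_pixels(raster_spec: RasterSpec, grid_spec: GridSpec):
    from .stimuli import render_amsler

    _, mask = render_amsler(grid_spec, raster_spec)
    X, Y = raster_spec.pixel_center_grid()
    return X[mask], Y[mask], int(mask.sum())


def corrective_assessment(affected_field: DistortionField,
                          participant: SyntheticParticipant,
                          ranges: TemplateRanges = DEFAULT_RANGES,
                          budget: int = 800) -> CalibrationResult:
    """Tune a corrective field on the affected eye until the distortion
    disappears.

    A default geometric corrective kernel (mid-range defaults, zero
    amplitudes) is drawn on the affected eye; the participant's reported
    residual distortion drives a derivative-free simplex search over the
    corrective parameters — the computational analogue of the subject
    twiddling parameter sliders.  Only the affected-eye (monocular) percept
    is ever queried; the contralateral display stays off.
    """
    thresholds = reference_thresholds(ranges, _GRID, _RASTER)
    ref = thresholds.grid_ref_metric
    line_pixels = _line_pixels(_RASTER, _GRID)

    if len(affected_field) == 0:
        return CalibrationResult(DistortionField((), eye=affected_field.eye),
                                 [0.0], True, 0, final_score=0)

    n_kernels = len(affected_field)
    alpha = ranges.boundary_alpha

    def make_field(p) -> DistortionField:
        kernels = []
        for i in range(n_kernels):
            cx, cy, sig, rho, s = p[5 * i : 5 * i + 5]
            kernels.append(DistortionKernel(
                (cx, cy), max(abs(sig), 1e-2), 0.0, rho, max(s, -0.9), alpha))
        return DistortionField(tuple(kernels), eye=affected_field.eye)

    state = {"n": 0, "best": math.inf, "trace": []}

    def f(p):
        m = _corrective_metric(affected_field, make_field(p), line_pixels, _GRID.pitch_deg)
        reported = participant.perceive(m, ref)
        state["n"] += 1
        if reported < state["best"]:
            state["best"] = reported
            state["trace"].append(reported)
        return reported

    # Coarse center scan first: with zero corrective amplitude the percept is
    # flat in the center parameters, so probe a lattice of centers with a
    # small rotation amplitude of either sign and start where the report is
    # best (the analogue of the subject dragging the corrective blob around).
    sig0 = _mid(ranges.sigma_deg)
    ecc = ranges.center_eccentricity_deg[1]
    probes = np.linspace(-ecc, ecc, 5)
    best_center, best_rho, best_rep = (0.0, 0.0), 0.0, math.inf
    for cx in probes:
        for cy in probes:
            for rho in (-0.15, 0.15):
                probe = DistortionField(
                    (DistortionKernel((cx, cy), sig0, 0.0, rho, 0.0,
                                      ranges.boundary_alpha),) * 1,
                    eye=affected_field.eye)
                m = _corrective_metric(affected_field, probe, line_pixels, _GRID.pitch_deg)
                rep = participant.perceive(m, ref)
                state["n"] += 1
                if rep < best_rep:
                    best_center, best_rho, best_rep = (cx, cy), rho, rep

    x0, simplex_steps = [], []
    for _ in range(n_kernels):
        x0.extend([best_center[0], best_center[1], sig0, best_rho, 0.0])
        simplex_steps.extend([1.0, 1.0, 0.5, 0.2, 0.12])
    x0 = np.asarray(x0, dtype=float)
    simplex_steps = np.asarray(simplex_steps)

    # simplex search with restarts: re-seed a shrunken simplex at the
    # incumbent until the query budget is spent or progress stalls
    x, best, success = x0, math.inf, False
    spread = 1.0
    while state["n"] < budget:
        simplex = np.vstack([x] + [x + spread * st * e
                                   for st, e in zip(simplex_steps, np.eye(x0.size))])
        res = minimize(f, x, method="Nelder-Mead",
                       options={"maxfev": budget - state["n"],
                                "initial_simplex": simplex,
                                "xatol": 1e-5, "fatol": 1e-12})
        success = bool(res.success)
        if res.fun >= best * (1.0 - 1e-3):
            if res.fun < best:
                best, x = float(res.fun), res.x
            break
        best, x = float(res.fun), res.x
        spread *= 0.3
    res_x = x
    fitted = make_field(res_x)
    final_metric = _corrective_metric(affected_field, fitted, line_pixels, _GRID.pitch_deg)
    final_score = to_score(participant.perceive(final_metric, ref), ref)
    state["n"] += 1
    return CalibrationResult(fitted, state["trace"], success, state["n"],
                             final_score=final_score)


def macular_hole_procedure(participant: SyntheticParticipant,
                           ranges: TemplateRanges = DEFAULT_RANGES,
                           step_sizes: StepSizes = StepSizes(),
                           hidden_field: DistortionField | None = None,
                           budget: int = 400) -> CalibrationResult:
    """The stepwise examiner protocol for a focal (macular-hole) distortion.

    The participant harbors a fixed hidden single-kernel distortion (drawn
    from ``ranges`` with the participant's seed unless given explicitly).
    Stages: (1) the subject directs a small dot to the distortion center;
    (2) the examiner grows a circle until the subject reports it covers the
    distorted area; (3) tangential rotation, clockwise first, reversing on a
    "worse" report; (4) radial contortion, inward first, reversing on a
    "worse" report.  Stages 3–4 are repeated with halved steps until the
    subject reports the distortion imperceptible (score 0) or the query
    budget is exhausted.  Deterministic given the participant seed.
    """
    if hidden_field is None:
        one = replace(ranges, n_kernels=(1, 1))
        hidden_field = random_metamorphopsia(participant.seed, one)
    log: list[str] = []
    thresholds = reference_thresholds(ranges, _GRID, _RASTER)
    ref = thresholds.grid_ref_metric
    line_pixels = _line_pixels(_RASTER, _GRID)
    state = {"n": 0}

    def metric(corrective: DistortionField | None) -> float:
        if corrective is None:
            corrective = DistortionField((), eye=hidden_field.eye)
        return _corrective_metric(hidden_field, corrective, line_pixels, _GRID.pitch_deg)

    def score(corrective) -> int:
        state["n"] += 1
        return to_score(participant.perceive(metric(corrective), ref), ref)

    if len(hidden_field) == 0 or score(None) == 0:
        return CalibrationResult(DistortionField((), eye="left"), [metric(None)],
                                 True, state["n"], final_score=0, log=["no distortion reported"])

    hidden = hidden_field.kernels[0]
    noise = participant.score_noise_sd

    def perceived_offset(point) -> tuple[float, float]:
        state["n"] += 1
        dx = hidden.center[0] - point[0]
        dy = hidden.center[1] - point[1]
        if noise > 0:
            dx += participant._rng.normal(0.0, noise * step_sizes.center_deg)
            dy += participant._rng.normal(0.0, noise * step_sizes.center_deg)
        return dx, dy

    # stage 1: center localization by directional feedback
    dot = [0.0, 0.0]
    for _ in range(200):
        if state["n"] >= budget:
            break
        dx, dy = perceived_offset(dot)
        if max(abs(dx), abs(dy)) <= step_sizes.center_deg / 2.0:
            log.append("center reported on target")
            break
        if abs(dx) >= abs(dy):
            dot[0] += math.copysign(step_sizes.center_deg, dx)
        else:
            dot[1] += math.copysign(step_sizes.center_deg, dy)
    center = (dot[0], dot[1])

    # stage 2: grow the circle until reported full coverage
    radius = step_sizes.radius_deg
    for _ in range(200):
        if state["n"] >= budget:
            break
        state["n"] += 1
        needed = math.hypot(hidden.center[0] - center[0],
                            hidden.center[1] - center[1]) + hidden.support_radius_deg
        if noise > 0:
            needed += participant._rng.normal(0.0, noise * step_sizes.radius_deg)
        if radius >= needed:
            log.append("coverage reported complete")
            break
        radius += step_sizes.radius_deg
    sigma = radius / ranges.boundary_alpha

    def corrective(rho, s) -> DistortionField:
        return DistortionField(
            (DistortionKernel(center, sigma, 0.0, rho, max(s, -0.9),
                              ranges.boundary_alpha),),
            eye=hidden_field.eye,
        )

    rho, s = 0.0, 0.0
    current = metric(corrective(rho, s))
    trace = [current]

    def line_search(value, step, first_direction, setter, stage: str):
        """1-D descent with direction reversal on the first 'worse' report."""
        nonlocal current
        direction = first_direction
        reversed_once = False
        accepted = False
        while state["n"] < budget:
            trial = value + direction * step
            cand = metric(setter(trial))
            state["n"] += 1
            verdict = participant.compare(cand, current, ref)
            if verdict < 0:
                value, current = trial, cand
                trace.append(current)
                accepted = True
                continue
            if not accepted and not reversed_once:
                direction = -direction
                reversed_once = True
                log.append(f"{stage}: direction reversed")
                continue
            break
        return value

    # Sign conventions, as seen by the viewer: a positive backward-sampling
    # angle rotates the *content* clockwise, and a positive radial stretch of
    # the sampling points contorts the content inward.  The examiner tries
    # content-clockwise rotation and inward contortion first, reversing on a
    # "worse" report.
    steps_rot, steps_con = step_sizes.rotation_rad, step_sizes.contortion
    for refinement in range(4):
        if state["n"] >= budget:
            break
        # stage 3: tangential rotation, content-clockwise first
        rho = line_search(rho, steps_rot, +1.0, lambda v: corrective(v, s), "rotation")
        if score(corrective(rho, s)) == 0:
            break
        # stage 4: radial contortion, inward first
        s = line_search(s, steps_con, +1.0, lambda v: corrective(rho, v), "contortion")
        if score(corrective(rho, s)) == 0:
            break
        steps_rot /= 2.0
        steps_con /= 2.0

    fitted = corrective(rho, s)
    final_score = to_score(participant.perceive(metric(fitted), ref), ref)
    state["n"] += 1
    return CalibrationResult(fitted, trace, state["n"] < budget, state["n"],
                             final_score=final_score, log=log)
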