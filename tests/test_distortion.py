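"""Distortion kernels, field rasterization, warping, inversion, correction."""

import math

import numpy as np
import pytest

from metamorphsim import (
    DistortionField,
    displacement_at,
    distortion_extent,
    field_displacement,
    fit_corrective_field,
    invert_displacement,
    kernel_weight,
    load_template,
    make_kernel,
    render_maps,
    save_template,
    warp_image,
)
from metamorphsim.distortion import residual_displacement


def oracle_offset(kernel, px, py):
    """Independent scalar evaluation of the kernel's backward offset.

    Rotate-then-scale: sample = center + Rot(theta(r)) v (1 + s g(r)) with
    g(r) = exp(-r^2/2 sigma^2) T(r), theta(r) = rho (r/sigma) exp(1/2 -
    r^2/2 sigma^2) T(r), T a smoothstep from 1 to 0 over
    [(alpha-1/2) sigma, alpha sigma].
    """
    vx, vy = px - kernel.center[0], py - kernel.center[1]
    r = math.hypot(vx, vy)
    sig, al = kernel.sigma_deg, kernel.boundary_alpha
    t = min(max((r - (al - 0.5) * sig) / (0.5 * sig), 0.0), 1.0)
    T = 1.0 - t * t * (3.0 - 2.0 * t)
    q = r * r / (2.0 * sig * sig)
    g = math.exp(-q) * T
    theta = kernel.rotation_strength_rad * (r / sig) * math.exp(0.5 - q) * T
    sc = 1.0 + kernel.radial_stretch * g
    c, s = math.cos(theta), math.sin(theta)
    return (c * vx - s * vy) * sc - vx, (s * vx + c * vy) * sc - vy


class TestKernelConstruction:
    def test_pass_through_fields(self):
        k = make_kernel((0, 0), 2.0, 0.5, 0.3, 0.2, 3.0)
        assert k.center == (0.0, 0.0)
        assert (k.sigma_deg, k.luminance_loss) == (2.0, 0.5)
        assert (k.rotation_strength_rad, k.radial_stretch, k.boundary_alpha) == (0.3, 0.2, 3.0)

    def test_full_luminance_loss_allowed(self):
        assert make_kernel((0, 0), 1.0, luminance_loss=1.0).luminance_loss == 1.0

    @pytest.mark.parametrize("kwargs, name", [
        (dict(sigma_deg=0.0), "sigma_deg"),
        (dict(sigma_deg=1.0, luminance_loss=1.5), "luminance_loss"),
        (dict(sigma_deg=1.0, luminance_loss=-0.1), "luminance_loss"),
        (dict(sigma_deg=1.0, radial_stretch=-1.0), "radial_stretch"),
        (dict(sigma_deg=1.0, boundary_alpha=0.5), "boundary_alpha"),
    ])
    def test_out_of_range_rejected_naming_field(self, kwargs, name):
        with pytest.raises(ValueError, match=name):
            make_kernel((0, 0), **kwargs)


class TestKernelWeight:
    def test_closed_forms(self):
        k = make_kernel((1.0, -2.0), 2.0, boundary_alpha=3.0)
        assert kernel_weight(k, (1.0, -2.0)) == 1.0
        assert kernel_weight(k, (3.0, -2.0)) == pytest.approx(math.exp(-0.5), abs=1e-12)
        assert kernel_weight(k, (1.0 + 6.01, -2.0)) == 0.0

    def test_support_is_closed_disk(self):
        k = make_kernel((0, 0), 1.5, boundary_alpha=2.0)
        r_b = k.support_radius_deg
        assert kernel_weight(k, (r_b - 1e-6, 0.0)) >= 0.0
        assert kernel_weight(k, (r_b + 1e-9, 0.0)) == 0.0


class TestDisplacement:
    def test_zero_amplitudes_give_zero_everywhere(self, rng):
        f = DistortionField((make_kernel((0.5, 0.5), 2.0, luminance_loss=0.7),))
        for _ in range(10):
            p = rng.uniform(-8, 8, size=2)
            assert np.allclose(displacement_at(f, p), 0.0)

    def test_zero_outside_support(self, canonical_field):
        k = canonical_field.kernels[0]
        p = (k.center[0] + k.support_radius_deg + 0.01, k.center[1])
        assert np.all(displacement_at(canonical_field, p) == 0.0)

    def test_radial_only_displacement_is_radial(self):
        """s-only kernel displaces along the radius; matches the scalar oracle."""
        k = make_kernel((0, 0), 2.0, radial_stretch=0.2)
        f = DistortionField((k,))
        d = displacement_at(f, (2.0, 0.0))  # +x axis at r = sigma
        ox, oy = oracle_offset(k, 2.0, 0.0)
        assert d[1] == pytest.approx(0.0, abs=1e-12)
        assert d[0] == pytest.approx(ox, abs=1e-12)
        assert oy == pytest.approx(0.0, abs=1e-12)

    def test_matches_scalar_oracle_at_sample_points(self, rng):
        k = make_kernel((0.7, -1.2), 1.8, 0.4, -0.35, 0.25, 3.0)
        f = DistortionField((k,))
        for _ in range(10):
            px, py = rng.uniform(-6, 6, size=2)
            d = displacement_at(f, (px, py))
            ox, oy = oracle_offset(k, px, py)
            assert d[0] == pytest.approx(ox, abs=1e-12)
            assert d[1] == pytest.approx(oy, abs=1e-12)

    def test_multi_kernel_displacements_add(self, rng):
        k1 = make_kernel((0.0, 0.0), 2.0, rotation_strength_rad=0.3)
        k2 = make_kernel((1.0, 1.0), 1.5, radial_stretch=-0.2)
        f12 = DistortionField((k1, k2))
        p = (0.8, 0.4)
        d1 = displacement_at(DistortionField((k1,)), p)
        d2 = displacement_at(DistortionField((k2,)), p)
        assert np.allclose(displacement_at(f12, p), d1 + d2, atol=1e-14)


class TestRenderMaps:
    def test_empty_field_is_identity_maps(self, raster):
        disp, lum = render_maps(DistortionField(()), raster)
        assert np.all(disp == 0.0)
        assert np.all(lum == 1.0)

    def test_pointwise_agreement_with_displacement_at(self, canonical_field, raster, rng):
        disp, _ = render_maps(canonical_field, raster)
        X, Y = raster.pixel_center_grid()
        s = raster.deg_per_px
        for _ in range(20):
            j, i = rng.integers(0, 128, size=2)
            d_deg = displacement_at(canonical_field, (X[j, i], Y[j, i]))
            assert disp[j, i, 0] == pytest.approx(d_deg[0] / s, abs=1e-9)
            assert disp[j, i, 1] == pytest.approx(-d_deg[1] / s, abs=1e-9)

    def test_coincident_luminance_losses_multiply(self, raster):
        X, Y = raster.pixel_center_grid()
        c = (X[64, 64], Y[64, 64])  # an exact pixel center
        f = DistortionField((
            make_kernel(c, 2.0, luminance_loss=0.5),
            make_kernel(c, 2.0, luminance_loss=0.5),
        ))
        _, lum = render_maps(f, raster)
        assert lum[64, 64] == pytest.approx(0.25, abs=1e-12)

    def test_kernel_order_invariance(self, raster, rng):
        kernels = tuple(
            make_kernel(rng.uniform(-3, 3, 2), rng.uniform(1, 2.5),
                        rng.uniform(0, 0.8), rng.uniform(-0.5, 0.5),
                        rng.uniform(-0.2, 0.3))
            for _ in range(4)
        )
        disp1, lum1 = render_maps(DistortionField(kernels), raster)
        perm = (kernels[2], kernels[0], kernels[3], kernels[1])
        disp2, lum2 = render_maps(DistortionField(perm), raster)
        assert np.max(np.abs(disp1 - disp2)) < 1e-12
        assert np.max(np.abs(lum1 - lum2)) < 1e-12

    def test_locality_outside_supports(self, seeded_fields, raster):
        """Displacement is exactly 0 and gain exactly 1 off-support."""
        f = seeded_fields[2]
        disp, lum = render_maps(f, raster)
        X, Y = raster.pixel_center_grid()
        outside = np.ones(raster.shape, dtype=bool)
        for k in f.kernels:
            outside &= np.hypot(X - k.center[0], Y - k.center[1]) > k.support_radius_deg
        assert outside.any()
        assert np.all(disp[outside] == 0.0)
        assert np.all(lum[outside] == 1.0)

    def test_luminance_gain_bounds(self, seeded_fields, raster):
        for f in seeded_fields[:5]:
            _, lum = render_maps(f, raster)
            floor = np.prod([1.0 - k.luminance_loss for k in f.kernels])
            assert lum.min() >= floor - 1e-12
            assert lum.max() <= 1.0 + 1e-12


class TestWarpImage:
    def test_identity_is_bit_exact(self, raster, rng):
        disp, lum = render_maps(DistortionField(()), raster)
        for _ in range(3):
            img = rng.integers(0, 256, size=(128, 128, 3), dtype=np.uint8)
            out = warp_image(img, disp, lum)
            assert out.dtype == img.dtype
            assert np.array_equal(out, img)

    def test_constant_image_unchanged_by_any_displacement(self, canonical_field, raster):
        disp, _ = render_maps(canonical_field, raster)
        img = np.full((128, 128), 137, dtype=np.uint8)
        out = warp_image(img, disp, np.ones(raster.shape))
        assert np.array_equal(out, img)

    def test_full_luminance_loss_blacks_out_center(self, raster):
        X, Y = raster.pixel_center_grid()
        f = DistortionField((make_kernel((X[64, 64], Y[64, 64]), 2.0, luminance_loss=1.0),))
        disp, lum = render_maps(f, raster)
        img = np.full((128, 128), 255, dtype=np.uint8)
        assert warp_image(img, disp, lum)[64, 64] == 0

    def test_shape_mismatch_raises(self, raster):
        disp, lum = render_maps(DistortionField(()), raster)
        with pytest.raises(ValueError, match="shape"):
            warp_image(np.zeros((64, 64)), disp, lum)


class TestInversion:
    def test_zero_map_inverts_to_zero(self):
        z = np.zeros((32, 32, 2))
        assert np.array_equal(invert_displacement(z, tol=1e-6), z)

    def test_forward_inverse_residual_below_half_pixel(self, canonical_field, raster):
        disp, _ = render_maps(canonical_field, raster)
        inv = invert_displacement(disp, tol=0.05)
        H, W = raster.shape
        jj, ii = np.meshgrid(np.arange(H, dtype=float), np.arange(W, dtype=float),
                             indexing="ij")
        from metamorphsim.distortion import _sample_map

        dx, dy = _sample_map(disp, ii + inv[..., 0], jj + inv[..., 1])
        residual = np.hypot(dx + inv[..., 0], dy + inv[..., 1])
        assert residual.max() < 0.5

    def test_small_amplitude_inverse_is_negated_forward(self, raster):
        f = DistortionField((make_kernel((0, 0), 2.5, 0.0, 0.01, 0.005),))
        disp, _ = render_maps(f, raster)
        inv = invert_displacement(disp, tol=1e-4)
        peak = np.abs(disp).max()
        assert np.abs(inv + disp).max() < 0.01 * peak

    def test_nonconvergence_reports_residual(self, canonical_field, raster):
        disp, _ = render_maps(canonical_field, raster)
        with pytest.raises(RuntimeError, match="residual"):
            invert_displacement(disp, tol=1e-9, max_iter=1)


class TestCorrectiveFit:
    def test_empty_field_gives_zero_objective(self, raster):
        fit = fit_corrective_field(DistortionField(()), raster)
        assert fit.objective == 0.0
        assert len(fit.field) == 0

    def test_single_kernel_residual_under_5_percent(self, canonical_field, raster):
        fit = fit_corrective_field(canonical_field, raster, n_kernels=1, budget=2000)
        X, Y = raster.pixel_center_grid()
        dx, dy = field_displacement(canonical_field, X, Y)
        uncorrected = math.sqrt(float(np.mean(dx**2 + dy**2)))
        rx, ry = residual_displacement(canonical_field, fit.field, X, Y)
        corrected = math.sqrt(float(np.mean(rx**2 + ry**2)))
        assert corrected < 0.05 * uncorrected

    def test_objective_never_exceeds_zero_corrective(self, seeded_fields, raster):
        f = seeded_fields[0]
        fit = fit_corrective_field(f, raster, n_kernels=1, budget=300)
        X, Y = raster.pixel_center_grid()
        X, Y = X[::4, ::4].ravel(), Y[::4, ::4].ravel()
        dx, dy = field_displacement(f, X, Y)
        zero_obj = float(np.mean(dx * dx + dy * dy))
        assert fit.objective <= zero_obj + 1e-15


class TestExtent:
    def test_single_kernel_extent(self):
        f = DistortionField((make_kernel((1.0, 2.0), 2.0, 0.5, boundary_alpha=3.0),))
        center, radius = distortion_extent(f)
        assert np.allclose(center, (1.0, 2.0))
        assert radius == pytest.approx(6.0)

    def test_symmetric_pair_centers_at_origin(self):
        f = DistortionField((
            make_kernel((-1.0, 0.0), 1.0, 0.5, 0.2, 0.1),
            make_kernel((1.0, 0.0), 1.0, 0.5, 0.2, 0.1),
        ))
        center, _ = distortion_extent(f)
        assert np.allclose(center, (0.0, 0.0), atol=1e-12)

    def test_disk_covers_all_nonzero_weight_pixels(self, raster, rng):
        from metamorphsim import kernel_weight

        f = DistortionField(tuple(
            make_kernel(rng.uniform(-3, 3, 2), rng.uniform(1.0, 2.0),
                        rng.uniform(0.2, 0.8), rng.uniform(-0.5, 0.5),
                        rng.uniform(-0.2, 0.3))
            for _ in range(3)
        ))
        center, radius = distortion_extent(f)
        X, Y = raster.pixel_center_grid()
        for j in range(0, 128, 3):
            for i in range(0, 128, 3):
                p = (X[j, i], Y[j, i])
                if any(kernel_weight(k, p) > 0 for k in f.kernels):
                    assert math.hypot(p[0] - center[0], p[1] - center[1]) <= radius + 1e-9

    def test_empty_field_raises(self):
        with pytest.raises(ValueError):
            distortion_extent(DistortionField(()))


class TestTemplateIO:
    @pytest.mark.parametrize("suffix", ["yaml", "json"])
    def test_round_trip(self, canonical_field, tmp_path, suffix):
        path = tmp_path / f"t.{suffix}"
        save_template(canonical_field, path)
        assert load_template(path) == canonical_field

    def test_unknown_field_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("eye: left\nkernels:\n- center: [0, 0]\n  sigma_deg: 1.0\n  wobble: 3\n")
        with pytest.raises(ValueError, match="wobble"):
            load_template(path)
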