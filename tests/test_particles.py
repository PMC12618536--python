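"""Backgrounds, detection, cross-sections, forward model and inversion."""

import numpy as np
import pandas as pd
import pytest

from bqsm.model import ComplexField
from bqsm.particles import (
    cross_section,
    detect_particles,
    differential_sa,
    flow_background,
    forward_model,
    invert_ri_size,
    normalize_cross_sections,
    static_background,
)
from bqsm.reconstruction import SAImage


def _sa(values, cfg):
    return SAImage(values=values, channel="fs", sample_plane_pixel=cfg.sample_pixel)


def _field(values, cfg, channel="fs"):
    return ComplexField(
        values=np.asarray(values, dtype=complex),
        channel=channel,
        sample_plane_pixel=cfg.sample_pixel,
        wavelength=cfg.wavelength,
        medium_index=cfg.medium_index,
    )


class TestBackgrounds:
    def test_flow_background_of_constant_stack(self):
        stack = np.ones((500, 8, 8), dtype=complex) * (2 + 1j)
        bg = flow_background(stack, 250)
        np.testing.assert_allclose(bg, 2 + 1j)

    def test_flow_background_uses_outer_hundred_frame_blocks(self):
        """For t = 250 in a 500-frame stack the window is frames 50-149 and
        351-450, whose frame-index means are 99.5 and 400.5."""
        stack = np.arange(500, dtype=float)[:, None, None] * np.ones((1, 4, 4))
        bg = flow_background(stack.astype(complex), 250)
        assert bg[0, 0].real == pytest.approx((99.5 + 400.5) / 2)

    def test_flow_background_window_bounds_rejected(self):
        stack = np.ones((300, 4, 4), dtype=complex)
        with pytest.raises(ValueError, match="frames"):
            flow_background(stack, 50)

    def test_flow_background_recovers_static_field(self):
        """A bead present only near the central frame does not contaminate
        the outer-window average."""
        rng = np.random.default_rng(4)
        static = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        stack = np.tile(static, (401, 1, 1))
        stack[150:251] += 0.5  # bead signal within +-50 frames of t = 200
        bg = flow_background(stack, 200)
        np.testing.assert_allclose(bg, static, atol=1e-12)

    def test_static_background_of_identical_stack(self):
        frame = np.full((8, 8), 1.5 + 0.5j)
        np.testing.assert_allclose(static_background(np.tile(frame, (10, 1, 1))),
                                   frame)

    def test_static_background_zero_stack(self):
        np.testing.assert_allclose(
            static_background(np.zeros((5, 4, 4), dtype=complex)), 0.0
        )

    def test_static_background_suppresses_phase_walking_bead(self):
        """A bead whose scattered phase random-walks averages out of the
        long-time mean by at least 10x relative to a single frame."""
        rng = np.random.default_rng(9)
        phases = np.exp(1j * rng.uniform(0, 2 * np.pi, 400))
        bead = 0.2 * phases[:, None, None] * np.ones((1, 8, 8))
        stack = 1.0 + bead
        bg = static_background(stack)
        residual = np.abs(bg - 1.0).max()
        assert residual < 0.2 / 10

    def test_static_background_needs_two_frames(self):
        with pytest.raises(ValueError, match="2 frames"):
            static_background(np.ones((1, 4, 4), dtype=complex))


class TestDifferentialSA:
    def test_no_particle_change_gives_zero(self, cfg256):
        e = _field(np.ones((16, 16)), cfg256)
        sa = differential_sa(e, e, e, 1.0)
        assert np.all(sa.values == 0)

    def test_unit_contrast(self, cfg256):
        e_p = _field(np.full((8, 8), 2.0), cfg256)
        e_np = _field(np.ones((8, 8)), cfg256)
        e_bg = _field(np.ones((8, 8)), cfg256)
        np.testing.assert_allclose(differential_sa(e_p, e_np, e_bg, 1.0).values, 1.0)

    def test_differential_isolates_bead_over_static_speckle(self, cfg256):
        """Static substrate speckle cancels in the particle/no-particle
        difference, so the differential SA peak matches the bead-only SA."""
        rng = np.random.default_rng(6)
        speckle = 1.0 + 0.2 * (
            rng.standard_normal((64, 64)) + 1j * rng.standard_normal((64, 64))
        )
        rr, cc = np.mgrid[0:64, 0:64]
        bead = 0.05 * np.exp(-((rr - 32) ** 2 + (cc - 32) ** 2) / 8.0)
        e_np = _field(speckle, cfg256)
        e_p = _field(speckle + bead, cfg256)
        e_bg = _field(np.ones((64, 64)), cfg256)
        sa = differential_sa(e_p, e_np, e_bg, 1.0)
        assert sa.values.max() == pytest.approx(0.05, rel=0.05)

    def test_shape_mismatch_rejected(self, cfg256):
        a = _field(np.ones((8, 8)), cfg256)
        b = _field(np.ones((16, 16)), cfg256)
        with pytest.raises(ValueError, match="co-registered"):
            differential_sa(a, b, a, 1.0)


class TestDetection:
    def test_blank_image_gives_no_detections(self, cfg256):
        assert detect_particles(_sa(np.zeros((32, 32)), cfg256), 0.01, 5) == []

    def test_single_blob_localized_within_half_pixel(self, cfg256):
        rr, cc = np.mgrid[0:64, 0:64].astype(float)
        img = 0.2 * np.exp(-((rr - 30.3) ** 2 + (cc - 41.7) ** 2) / (2 * 2.0**2))
        centers = detect_particles(_sa(img, cfg256), 0.05, 5)
        assert len(centers) == 1
        assert np.hypot(centers[0][0] - 30.3, centers[0][1] - 41.7) < 0.5

    def test_two_blobs_at_ten_pixels_both_found(self, cfg256):
        rr, cc = np.mgrid[0:64, 0:64].astype(float)
        img = 0.2 * np.exp(-((rr - 30) ** 2 + (cc - 20) ** 2) / 4.0)
        img += 0.2 * np.exp(-((rr - 30) ** 2 + (cc - 30) ** 2) / 4.0)
        centers = detect_particles(_sa(img, cfg256), 0.05, 5)
        assert len(centers) == 2

    def test_threshold_validation(self, cfg256):
        with pytest.raises(ValueError):
            detect_particles(_sa(np.zeros((8, 8)), cfg256), 0.0, 5)


class TestCrossSection:
    def test_zero_image_gives_zero(self, cfg256):
        sigma, _ = cross_section(_sa(np.zeros((32, 32)), cfg256), (16, 16),
                                 mode="pixel")
        assert sigma == 0.0

    def test_exact_gaussian_closed_form(self, cfg256):
        """A = 0.1, s = 2 px: closed form A^2 pi s^2 = 0.04 pi ~ 0.1257 px^2;
        the pixel-sum route agrees within 0.5%."""
        rr, cc = np.mgrid[0:64, 0:64].astype(float)
        img = 0.1 * np.exp(-((rr - 32) ** 2 + (cc - 32) ** 2) / (2 * 2.0**2))
        sigma_g, fit = cross_section(_sa(img, cfg256), (32.0, 32.0), mode="gauss",
                                     roi_radius=16)
        assert sigma_g == pytest.approx(0.04 * np.pi, rel=5e-3)
        assert fit[0] == pytest.approx(0.1, rel=1e-3)
        sigma_p, _ = cross_section(_sa(img, cfg256), (32.0, 32.0), mode="pixel",
                                   roi_radius=16)
        assert sigma_p == pytest.approx(sigma_g, rel=5e-3)

    def test_gauss_mode_suppresses_constant_background(self, cfg256):
        rr, cc = np.mgrid[0:64, 0:64].astype(float)
        img = 0.02 + 0.1 * np.exp(-((rr - 32) ** 2 + (cc - 32) ** 2) / 8.0)
        sigma, _ = cross_section(_sa(img, cfg256), (32.0, 32.0), mode="gauss",
                                 roi_radius=16)
        assert sigma == pytest.approx(0.04 * np.pi, rel=0.01)

    def test_adaptive_pixel_region(self, cfg256):
        rr, cc = np.mgrid[0:64, 0:64].astype(float)
        img = 0.1 * np.exp(-((rr - 32) ** 2 + (cc - 32) ** 2) / 8.0)
        sigma, _ = cross_section(_sa(img, cfg256), (32.0, 32.0), mode="pixel",
                                 roi_radius=20, adaptive=True)
        assert sigma == pytest.approx(0.04 * np.pi, rel=0.05)

    def test_center_outside_image_rejected(self, cfg256):
        with pytest.raises(ValueError, match="outside"):
            cross_section(_sa(np.zeros((16, 16)), cfg256), (20, 2))


class TestNormalization:
    def test_reference_population_maps_to_unit_mean(self):
        df = pd.DataFrame({
            "particle": [0, 0, 1, 1],
            "sigma_fs": [1.0, 3.0, 4.0, 4.0],
            "sigma_bs": [0.5, 1.5, 2.0, 2.0],
        })
        out = normalize_cross_sections(df, 3.0, 1.5)
        assert len(out) == 2  # temporal average per particle first
        assert out["sigma_fs_norm"].mean() == pytest.approx(1.0)
        assert out["sigma_bs_norm"].mean() == pytest.approx(1.0)

    def test_scaling_is_linear(self):
        df = pd.DataFrame({"sigma_fs": [2.0], "sigma_bs": [1.0]})
        out1 = normalize_cross_sections(df, 1.0, 1.0, particle_column=None)
        out2 = normalize_cross_sections(df * 2, 1.0, 1.0, particle_column=None)
        assert out2["sigma_fs_norm"].iloc[0] == 2 * out1["sigma_fs_norm"].iloc[0]

    def test_empty_records(self):
        df = pd.DataFrame({"sigma_fs": [], "sigma_bs": []})
        assert len(normalize_cross_sections(df, 1.0, 1.0)) == 0

    def test_nonpositive_reference_rejected(self):
        df = pd.DataFrame({"sigma_fs": [1.0], "sigma_bs": [1.0]})
        with pytest.raises(ValueError):
            normalize_cross_sections(df, 0.0, 1.0)


class TestForwardModel:
    def test_index_matched_sphere_does_not_scatter(self, cfg256):
        sf, sb = forward_model(1.33, 100.0, cfg256)
        assert sf == 0.0 and sb == 0.0

    def test_rayleigh_fore_aft_symmetry(self, cfg256):
        """20-nm silica: forward and backward hemispheres receive equal
        power within 2%."""
        sf, sb = forward_model(1.43, 20.0, cfg256)
        assert sf / sb == pytest.approx(1.0, rel=0.02)

    def test_rayleigh_sixth_power_scaling(self, cfg256):
        s20 = forward_model(1.43, 20.0, cfg256)
        s40 = forward_model(1.43, 40.0, cfg256)
        for a, b in zip(s40, s20):
            assert a / b == pytest.approx(64.0, rel=0.05)

    def test_fs_monotone_in_diameter_to_400nm(self, cfg256):
        d = np.arange(20.0, 401.0, 5.0)
        for n in (1.38, 1.45, 1.60):
            sf, _ = forward_model(n, d, cfg256)
            assert np.all(np.diff(sf) > 0)

    def test_bs_monotone_in_rayleigh_regime(self, cfg256):
        """The backward-cap integral oscillates for Mie-regime sizes (the
        backward channel saturates for large objects); monotonicity holds
        through the Rayleigh regime."""
        d = np.arange(20.0, 201.0, 5.0)
        for n in (1.38, 1.45, 1.60):
            _, sb = forward_model(n, d, cfg256)
            assert np.all(np.diff(sb) > 0)

    def test_monotone_in_index_contrast_at_small_d(self, cfg256):
        sigmas = [forward_model(n, 50.0, cfg256)[0]
                  for n in (1.35, 1.40, 1.45, 1.50)]
        assert np.all(np.diff(sigmas) > 0)

    def test_invalid_inputs_rejected(self, cfg256):
        with pytest.raises(ValueError):
            forward_model(1.43, -5.0, cfg256)
        with pytest.raises(ValueError):
            forward_model(1.20, 100.0, cfg256)


class TestInversion:
    def test_silica_round_trip(self, cfg256, model_grid):
        """Noise-free forward model of a 203-nm, n = 1.43 bead, normalized
        to the 150-nm polystyrene reference, inverts back exactly."""
        ref = forward_model(1.598, 151.0, cfg256)
        true = forward_model(1.43, 203.0, cfg256)
        res = invert_ri_size(true[0] / ref[0], true[1] / ref[1], model_grid, ref)
        assert res["n"] == pytest.approx(1.43, abs=2e-3)
        assert res["d"] == pytest.approx(203.0, abs=1.0)
        assert res["flags"] == []

    def test_reference_input_is_a_fixed_point(self, cfg256, model_grid):
        ref = forward_model(1.598, 151.0, cfg256)
        res = invert_ri_size(1.0, 1.0, model_grid, ref)
        assert res["n"] == pytest.approx(1.598, abs=2e-3)
        assert res["d"] == pytest.approx(151.0, abs=1.0)

    def test_random_round_trips_are_self_consistent(self, cfg256, model_grid):
        """At 10 random in-bounds points the inversion reproduces the input
        cross-section pair exactly (self-consistency); over the injective
        domain (d <= 250 nm) it also recovers (n, d) themselves.  Beyond
        that the backward-channel Mie oscillations make distinct (n, d)
        pairs share a cross-section pair, so only sigma-space exactness is
        meaningful."""
        rng = np.random.default_rng(1)
        ref = forward_model(1.598, 151.0, cfg256)
        for _ in range(10):
            n = rng.uniform(1.36, 1.64)
            d = rng.uniform(50.0, 250.0)
            s = forward_model(n, d, cfg256)
            res = invert_ri_size(s[0] / ref[0], s[1] / ref[1], model_grid, ref)
            s_back = forward_model(res["n"], res["d"], cfg256)
            assert np.log(s_back[0] / s[0]) ** 2 + np.log(s_back[1] / s[1]) ** 2 < 1e-8
            assert res["n"] == pytest.approx(n, abs=5e-3)
            assert res["d"] == pytest.approx(d, abs=2.0)
        # an ambiguous Mie-regime point still closes exactly in sigma-space
        s = forward_model(1.503, 287.6, cfg256)
        res = invert_ri_size(s[0] / ref[0], s[1] / ref[1], model_grid, ref)
        s_back = forward_model(res["n"], res["d"], cfg256)
        assert np.log(s_back[0] / s[0]) ** 2 + np.log(s_back[1] / s[1]) ** 2 < 1e-8

    def test_bounds_flag_boundary_estimates(self, cfg256, model_grid):
        """An input generated outside the allowed index range pins the
        estimate to the bound and flags it."""
        s = forward_model(1.60, 150.0, cfg256)
        ref = forward_model(1.598, 151.0, cfg256)
        res = invert_ri_size(s[0] / ref[0], s[1] / ref[1], model_grid, ref,
                             bounds=(1.38, 1.54))
        assert res["n"] <= 1.54 + 1e-9
        assert "boundary estimate" in res["flags"]

    def test_uncertainty_propagation_scales_with_input_error(self, cfg256,
                                                             model_grid):
        ref = forward_model(1.598, 151.0, cfg256)
        s = forward_model(1.45, 180.0, cfg256)
        res_lo = invert_ri_size(s[0] / ref[0], s[1] / ref[1], model_grid, ref,
                                sigma_rel_err=(0.05, 0.05))
        res_hi = invert_ri_size(s[0] / ref[0], s[1] / ref[1], model_grid, ref,
                                sigma_rel_err=(0.10, 0.10))
        assert res_hi["n_err"] == pytest.approx(2 * res_lo["n_err"], rel=1e-6)
        assert res_hi["d_err"] == pytest.approx(2 * res_lo["d_err"], rel=1e-6)
        assert res_lo["n_err"] > 0 and res_lo["d_err"] > 0

    def test_nonpositive_inputs_rejected(self, cfg256, model_grid):
        ref = forward_model(1.598, 151.0, cfg256)
        with pytest.raises(ValueError):
            invert_ri_size(0.0, 1.0, model_grid, ref)
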