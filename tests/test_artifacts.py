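"""Artifact models: absorption calibration, Poisson noise, rings, zingers."""

import numpy as np
import pytest
from scipy.stats import poisson as poisson_dist

from mstar.artifacts import (
    ArtifactConfig,
    apply_poisson,
    apply_ring,
    apply_zinger,
    calibrate_absorption,
    corrupt,
    make_ring_pattern,
)
from mstar.pipeline import ProjectionStack, fbp_reconstruct, make_angles, rearrange


def _stack(data):
    return ProjectionStack(np.asarray(data, dtype=np.float32), make_angles(len(data)))


class TestCalibrateAbsorption:
    def test_fixed_point_at_ln2(self):
        p = _stack(np.full((4, 8, 8), np.log(2.0)))
        _, c = calibrate_absorption(p, 0.5)
        assert c == pytest.approx(1.0, abs=1e-5)

    def test_uniform_ones_give_ln2(self):
        p = _stack(np.ones((4, 8, 8)))
        scaled, c = calibrate_absorption(p, 0.5)
        assert c == pytest.approx(np.log(2.0), abs=1e-5)
        assert np.allclose(scaled.data, np.log(2.0), atol=1e-4)

    def test_doubling_projections_halves_scale(self):
        p1 = _stack(np.ones((4, 8, 8)))
        p2 = _stack(2.0 * np.ones((4, 8, 8)))
        _, c1 = calibrate_absorption(p1, 0.5)
        _, c2 = calibrate_absorption(p2, 0.5)
        assert c2 == pytest.approx(c1 / 2.0, rel=1e-4)

    def test_mean_absorbed_fraction_hits_target(self, rng):
        data = rng.uniform(0.0, 3.0, size=(8, 16, 16)).astype(np.float32)
        data[0, :4] = 0.0  # rays missing the object are excluded
        scaled, _ = calibrate_absorption(_stack(data), 0.37)
        vals = scaled.data[scaled.data > 0]
        assert np.mean(1.0 - np.exp(-vals)) == pytest.approx(0.37, abs=1e-4)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            calibrate_absorption(_stack(np.zeros((2, 4, 4))))


class TestApplyPoisson:
    def test_identity_in_high_flux_limit(self, rng):
        p = _stack(rng.uniform(0.0, 5.0, size=(4, 16, 16)))
        out = apply_poisson(p, I0=1e12, seed=0)
        assert np.abs(out.data - p.data).max() < 1e-3

    def test_count_clipping_rule(self):
        p = _stack(np.full((1, 4, 4), 50.0))  # lam ~ 2e-20: always 0 counts
        out = apply_poisson(p, I0=100.0, seed=1)
        assert np.allclose(out.data, np.log(100.0), atol=1e-6)

    def test_monte_carlo_mean_matches_analytic(self):
        # p = 0 pixels at I0 = 100: compare the sample mean of -ln(k/I0)
        # against the exact expectation under k ~ max(Poisson(100), 1)
        I0, n_draws = 100.0, 100_000
        p = _stack(np.zeros((1, 250, 400)))
        out = apply_poisson(p, I0=I0, seed=3)
        ks = np.arange(1, 400)
        pmf = poisson_dist.pmf(ks, I0)
        pmf[0] += poisson_dist.pmf(0, I0)  # clipped to 1
        exact_mean = np.sum(pmf * (-np.log(ks / I0)))
        exact_var = np.sum(pmf * (np.log(ks / I0)) ** 2) - exact_mean**2
        se = np.sqrt(exact_var / n_draws)
        assert abs(out.data.mean() - exact_mean) < 3 * se

    def test_seed_determinism_and_positive_I0(self, rng):
        p = _stack(rng.uniform(0, 2, size=(2, 8, 8)))
        a = apply_poisson(p, 50.0, seed=9)
        b = apply_poisson(p, 50.0, seed=9)
        assert np.array_equal(a.data, b.data)
        with pytest.raises(ValueError):
            apply_poisson(p, 0.0, seed=0)


class TestRing:
    def test_zero_fraction_is_identity(self, rng):
        p = _stack(rng.uniform(0, 1, (4, 10, 10)))
        pattern = make_ring_pattern(10, 10, 0.0, 0.005, seed=0)
        assert np.array_equal(apply_ring(p, pattern).data, p.data)

    def test_exact_affected_pixel_count(self):
        pattern = make_ring_pattern(100, 100, 0.1, 0.005, seed=2)
        assert pattern.mask.sum() == 1000
        assert np.count_nonzero(pattern.offsets) == 1000

    def test_offset_std_matches_sigma(self):
        pattern = make_ring_pattern(200, 200, 0.5, 0.005, seed=3)
        affected = pattern.offsets[pattern.mask]
        assert affected.size >= 10_000
        assert np.std(affected) == pytest.approx(0.005, rel=0.10)

    def test_same_offsets_in_every_projection(self, rng):
        p = _stack(rng.uniform(0, 1, (6, 12, 12)))
        pattern = make_ring_pattern(12, 12, 0.2, 0.01, seed=4)
        out = apply_ring(p, pattern)
        diffs = out.data - p.data
        # identical offsets up to float32 rounding of the additions
        assert np.allclose(diffs, diffs[0][None], atol=1e-6)

    def test_commutes_with_rearrange(self, rng):
        p = _stack(rng.uniform(0, 1, (6, 12, 12)))
        pattern = make_ring_pattern(12, 12, 0.2, 0.01, seed=5)
        s_then = rearrange(apply_ring(p, pattern))
        # ring in sinogram space: add offsets[m, n] along the angle axis
        s_first = rearrange(p).data + pattern.offsets[:, None, :]
        assert np.array_equal(s_then.data, s_first)

    def test_shape_mismatch_rejected(self, rng):
        p = _stack(rng.uniform(0, 1, (2, 8, 8)))
        with pytest.raises(ValueError):
            apply_ring(p, make_ring_pattern(9, 9, 0.1, 0.01, seed=0))

    def test_ring_reconstruction_is_concentric(self):
        """Angle-constant offsets reconstruct to concentric structure.

        Only the mirror-even part of a detector-offset pattern is a
        consistent half-turn measurement (s(theta + pi, t) = s(theta, -t));
        the pattern is symmetrized accordingly before reconstruction so the
        arcs close into full rings.
        """
        from skimage.transform import warp_polar

        n = 96
        pattern = make_ring_pattern(1, n, 0.2, 0.01, seed=6)
        offsets = pattern.offsets + pattern.offsets[:, ::-1]
        p = ProjectionStack(
            np.broadcast_to(offsets, (128, 1, n)).copy(), make_angles(128)
        )
        rec = fbp_reconstruct(rearrange(p)).data[0]
        polar = warp_polar(rec.astype(np.float64), radius=n // 2 - 4)
        radial_profile = polar.mean(axis=0)
        angular_var = polar.var(axis=0).mean()
        radial_var = radial_profile.var()
        assert angular_var / radial_var < 0.1


class TestZinger:
    def test_zero_fraction_is_identity(self, rng):
        p = _stack(rng.uniform(0, 1, (10, 8, 8)))
        out = apply_zinger(p, 0.0, 0.01, 5.0, seed=0)
        assert np.array_equal(out.data, p.data)

    def test_exact_projection_and_pixel_counts(self, rng):
        p = _stack(rng.uniform(0, 1, (100, 20, 20)))
        out = apply_zinger(p, 0.1, 0.01, 5.0, seed=1)
        changed = out.data != p.data
        changed_projections = changed.any(axis=(1, 2))
        assert changed_projections.sum() == 10
        # round(0.01 * 400) = 4 pixels in each affected projection
        assert changed.sum() == 10 * 4

    def test_altered_pixels_take_value_v(self, rng):
        p = _stack(rng.uniform(0, 1, (20, 10, 10)))
        out = apply_zinger(p, 0.5, 0.05, 5.0, seed=2)
        changed = out.data != p.data
        assert np.all(out.data[changed] == 5.0)


class TestCorrupt:
    def test_all_disabled_is_identity(self, rng):
        p = _stack(rng.uniform(0, 1, (6, 8, 8)))
        cfg = ArtifactConfig(
            noise_enabled=False, ring_enabled=False, zinger_enabled=False, seed=0
        )
        assert np.array_equal(corrupt(p, cfg).data, p.data)

    def test_ring_only_constant_along_angle_axis(self, rng):
        p = _stack(rng.uniform(0, 1, (16, 8, 8)))
        cfg = ArtifactConfig(
            noise_enabled=False, zinger_enabled=False, P_ring=0.3, seed=5
        )
        diff = rearrange(corrupt(p, cfg)).data - rearrange(p).data
        # straight lines in the sinogram: no variation along the angle axis
        # (up to float32 rounding of the per-projection additions)
        assert np.allclose(diff, diff[:, :1, :], atol=1e-6)

    def test_seed_reproducibility_bitwise(self, rng):
        p = _stack(rng.uniform(0, 2, (20, 16, 16)))
        cfg = ArtifactConfig(I0=100, P_ring=0.1, P_zinger=0.001, P_proj=0.1, seed=42)
        assert np.array_equal(corrupt(p, cfg).data, corrupt(p, cfg).data)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            ArtifactConfig(P_ring=1.5).validate()
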