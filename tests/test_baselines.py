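"""Classical operators: median zinger removal, wavelet-Fourier ring
suppression, SSIM grid search."""

import numpy as np
import pytest

from mstar.artifacts import apply_ring, apply_zinger, make_ring_pattern
from mstar.baselines import (
    ClassicalParams,
    grid_search,
    remove_ring_wavelet_fft,
    remove_zinger_median,
)
from mstar.phantom import FoamSpec, generate_disk_phantom, generate_foam_phantom
from mstar.pipeline import (
    ProjectionStack,
    SinogramStack,
    fbp_reconstruct,
    forward_project,
    make_angles,
    rearrange,
)


def _foam_sinogram(n=64, n_a=128, rows=slice(30, 32)):
    vol = generate_foam_phantom(
        FoamSpec(grid_size=n, n_bubbles=40, bubble_radius_range=(2, 7), seed=3)
    )
    p = forward_project(vol, make_angles(n_a))
    return SinogramStack(rearrange(p).data[rows].copy(), p.angles)


class TestZingerMedian:
    def test_smooth_image_untouched(self):
        vol = generate_disk_phantom(32, 10, 0.5)
        p = forward_project(vol, make_angles(16))
        out = remove_zinger_median(p, dif=5.0, size=3)
        assert np.array_equal(out.data, p.data)

    def test_single_outlier_replaced_by_local_median(self):
        data = np.full((1, 9, 9), 0.7, dtype=np.float32)
        data[0, 4, 4] = 5.0
        p = ProjectionStack(data, make_angles(1))
        out = remove_zinger_median(p, dif=0.5, size=3)
        assert out.data[0, 4, 4] == pytest.approx(0.7)
        mask = np.ones((9, 9), bool)
        mask[4, 4] = False
        assert np.array_equal(out.data[0][mask], data[0][mask])

    def test_reference_parameters_accepted(self):
        ClassicalParams(dif=0.5, size=3, level=4, wname="sym5", sigma=8.0).validate()
        ClassicalParams(dif=0.5, size=3, level=4, wname="sym5", sigma=1.0).validate()

    def test_even_window_rejected(self):
        p = ProjectionStack(np.zeros((1, 8, 8)), make_angles(1))
        with pytest.raises(ValueError):
            remove_zinger_median(p, dif=0.5, size=4)

    def test_removes_simulated_zingers(self, rng):
        data = rng.uniform(0.4, 0.8, size=(20, 16, 16)).astype(np.float32)
        p = ProjectionStack(data, make_angles(20))
        corrupted = apply_zinger(p, 0.5, 0.02, 5.0, seed=1)
        cleaned = remove_zinger_median(corrupted, dif=0.5, size=3)
        assert cleaned.data.max() < 5.0


class TestRingWaveletFFT:
    def test_sigma_zero_limit_keeps_stripe_free_sinogram(self, rng):
        # sigma -> 0: the damping keeps everything except the exactly
        # angle-constant (k = 0) component of each detail band.  A strictly
        # stripe-free sinogram (zero mean along the angle axis in every
        # column) changes only through the small angle-DC leakage created
        # by the multilevel downsampling, while genuine stripes of similar
        # magnitude are attacked far harder.
        data = rng.normal(size=(2, 128, 64)).astype(np.float32)
        data -= data.mean(axis=1, keepdims=True)
        s = SinogramStack(data, make_angles(128))
        out = remove_ring_wavelet_fft(s, level=3, wname="sym5", sigma=0.0)
        rms_change = np.sqrt(np.mean((out.data - s.data) ** 2))
        rms = np.sqrt(np.mean(s.data**2))
        assert rms_change / rms < 0.06
        striped = data + rng.normal(size=(2, 1, 64)).astype(np.float32)
        out2 = remove_ring_wavelet_fft(
            SinogramStack(striped, s.angles), level=3, wname="sym5", sigma=0.0
        )
        change = np.sqrt(np.mean((out2.data - striped) ** 2))
        assert change > 3 * rms_change

    def test_constant_stripe_suppressed(self):
        # the filter is linear, so its action on the stripe alone is the
        # difference between filtering the striped and the clean sinogram
        s = _foam_sinogram(rows=slice(30, 31))
        col = 40
        striped = s.data.copy()
        striped[:, :, col] += 0.1
        out_clean = remove_ring_wavelet_fft(s, level=4, wname="sym5", sigma=8.0)
        out_striped = remove_ring_wavelet_fft(
            SinogramStack(striped, s.angles), level=4, wname="sym5", sigma=8.0
        )
        response = out_striped.data - out_clean.data
        profile = response[0].mean(axis=0)
        # residual stripe amplitude, background-subtracted
        residual = profile[col] - 0.5 * (profile[col - 2] + profile[col + 2])
        assert abs(residual) <= 0.1 * 0.1

    def test_shape_preserved_and_contractive_on_clean_input(self):
        # repeated application converges: the Fourier damping is a
        # contraction (each pass scales stripe-band components by g < 1),
        # so the second pass changes far less than the first
        s = _foam_sinogram()
        once = remove_ring_wavelet_fft(s, 4, "sym5", 8.0)
        twice = remove_ring_wavelet_fft(once, 4, "sym5", 8.0)
        assert once.data.shape == s.data.shape
        rms = np.sqrt(np.mean(once.data**2))
        first = np.sqrt(np.mean((once.data - s.data) ** 2))
        second = np.sqrt(np.mean((twice.data - once.data) ** 2))
        assert second / rms < 0.05
        assert second < 0.5 * first

    def test_too_few_angles_and_bad_wavelet(self):
        s = SinogramStack(np.zeros((1, 8, 16)), make_angles(8))
        with pytest.raises(ValueError):
            remove_ring_wavelet_fft(s, level=4)
        with pytest.raises(ValueError):
            remove_ring_wavelet_fft(s, level=2, wname="nosuchwavelet")


class TestGridSearch:
    @pytest.fixture(scope="class")
    def corrupted_toy_scan(self):
        # a structured (non-rotationally-symmetric) object with rings
        # strong enough to dominate the error budget: for a centered disk
        # the whole sinogram is angle-constant and any stripe filter would
        # remove the object itself
        vol = generate_foam_phantom(
            FoamSpec(grid_size=48, n_bubbles=25, bubble_radius_range=(2, 6), seed=8)
        )
        p = forward_project(vol, make_angles(128))
        pattern = make_ring_pattern(48, 48, 0.3, 0.5, seed=2)
        p_bad = apply_zinger(apply_ring(p, pattern), 0.3, 0.01, 5.0, seed=3)
        reference = fbp_reconstruct(rearrange(p))
        return p_bad, reference

    def test_single_candidate_returned(self, corrupted_toy_scan):
        p_bad, ref = corrupted_toy_scan
        grid = {"dif": [0.5], "sigma": [8.0]}
        best, table = grid_search(p_bad, ref, grid)
        assert best == ClassicalParams(dif=0.5, sigma=8.0)
        assert len(table) == 1

    def test_argmax_consistent_with_score_table(self, corrupted_toy_scan):
        p_bad, ref = corrupted_toy_scan
        grid = {"sigma": [1.0, 8.0], "level": [1, 2, 4]}
        best, table = grid_search(p_bad, ref, grid)
        best_row = max(table, key=lambda r: r["mean_ssim"])
        assert best.sigma == best_row["sigma"] and best.level == best_row["level"]

    def test_search_beats_unprocessed_reconstruction(self, corrupted_toy_scan):
        p_bad, ref = corrupted_toy_scan
        from mstar.metrics import evaluate_volume

        unprocessed = evaluate_volume(fbp_reconstruct(rearrange(p_bad)), ref)
        grid = {"sigma": [1.0, 8.0], "level": [1, 2]}
        _, table = grid_search(p_bad, ref, grid)
        assert max(r["mean_ssim"] for r in table) >= unprocessed.mean_ssim

    def test_empty_grid_rejected(self, corrupted_toy_scan):
        p_bad, ref = corrupted_toy_scan
        with pytest.raises(ValueError):
            grid_search(p_bad, ref, {})
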