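import numpy as np
import pytest

from boneseg.io_types import BinaryMask, Image2D
from boneseg.phantom import PhantomSpec, make_phantom
from boneseg.srad import (DegenerateRegionError, DiffusionState, SradParams,
                          diffusion_coefficient, estimate_speckle_scale, icov,
                          srad, srad_step)


def _icov_reference(arr):
    """Independent ICOV oracle: explicit loops, replicated borders."""
    arr = np.maximum(arr, 1e-6)
    h, w = arr.shape
    q = np.zeros_like(arr)
    for i in range(h):
        for j in range(w):
            c = arr[i, j]
            n = arr[max(i - 1, 0), j] - c
            s = arr[min(i + 1, h - 1), j] - c
            we = arr[i, max(j - 1, 0)] - c
            e = arr[i, min(j + 1, w - 1)] - c
            g2 = (n**2 + s**2 + we**2 + e**2) / 2.0 / c**2
            lap = (n + s + we + e) / c
            num = 0.5 * g2 - lap**2 / 16.0
            den = (1.0 + 0.25 * lap) ** 2
            q[i, j] = np.sqrt(max(num / den, 0.0)) if den > 0 else 0.0
    return q


class TestIcov:
    def test_constant_image_is_zero(self):
        q = icov(Image2D(np.full((16, 16), 7.0)))
        np.testing.assert_allclose(q, 0.0)

    def test_matches_loop_oracle_on_step_edge(self):
        arr = np.where(np.arange(8)[None, :] < 4, 50.0, 150.0) * np.ones((8, 1))
        q = icov(Image2D(arr))
        np.testing.assert_allclose(q, _icov_reference(arr), atol=1e-12)
        # maximal response on the edge columns, ~0 far from the edge
        assert q[:, 3:5].min() > 10 * q[:, 0].max()

    def test_scale_invariance(self, rng):
        arr = rng.uniform(10, 200, (16, 16))
        q1 = icov(Image2D(arr))
        q2 = icov(Image2D(7.0 * arr))
        np.testing.assert_allclose(q1, q2, rtol=1e-9)


class TestSpeckleScale:
    def test_constant_region_gives_zero(self):
        img = Image2D(np.full((8, 8), 5.0))
        region = BinaryMask(np.ones((8, 8), dtype=np.uint8))
        assert estimate_speckle_scale(img, region) == 0.0

    def test_hand_computed_coefficient_of_variation(self):
        # 16-pixel region with mean 5 and sample variance exactly 2
        d = np.sqrt(30.0) / 4.0
        arr = np.full((8, 8), 5.0)
        vals = np.array([5 - d, 5 + d] * 8)
        arr[0, :] = vals[:8]
        arr[1, :] = vals[8:]
        region = np.zeros((8, 8), dtype=np.uint8)
        region[:2, :] = 1
        q0 = estimate_speckle_scale(Image2D(arr), BinaryMask(region))
        assert q0 == pytest.approx(np.sqrt(2.0) / 5.0, rel=1e-12)

    def test_scale_invariance(self, rng):
        arr = rng.uniform(10, 100, (16, 16))
        region = BinaryMask(np.ones((16, 16), dtype=np.uint8))
        q1 = estimate_speckle_scale(Image2D(arr), region)
        q2 = estimate_speckle_scale(Image2D(3 * arr), region)
        assert q1 == pytest.approx(q2, rel=1e-12)

    def test_degenerate_region_rejected(self):
        img = Image2D(np.full((8, 8), 5.0))
        small = np.zeros((8, 8), dtype=np.uint8)
        small[0, :4] = 1
        with pytest.raises(DegenerateRegionError):
            estimate_speckle_scale(img, BinaryMask(small))


class TestDiffusionCoefficient:
    def test_equals_one_when_icov_matches_scale(self):
        q = np.full((8, 8), 0.37)
        np.testing.assert_allclose(diffusion_coefficient(q, 0.37), 1.0)

    def test_clamped_at_one_below_scale(self):
        # q=0, q0=0.5: raw value 1/(1 - 0.25/(0.25*1.25)) = 5, clamped to 1
        c = diffusion_coefficient(np.zeros((4, 4)), 0.5)
        np.testing.assert_allclose(c, 1.0)

    def test_inhibited_at_strong_edges(self):
        c = diffusion_coefficient(np.full((4, 4), 1e6), 0.1)
        assert np.all(c <= 1e-6) and np.all(c > 0)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            diffusion_coefficient(np.zeros((4, 4)), 0.0)


class TestSradStep:
    def test_constant_image_fixed_point(self):
        img = Image2D(np.full((32, 32), 42.0))
        state = DiffusionState(image=img)
        params = SradParams(n_iters=1)
        for _ in range(5):
            state = srad_step(state, params)
        np.testing.assert_array_equal(state.image.pixels, img.pixels)

    def test_variance_strictly_decreases_on_noisy_patch(self, rng):
        arr = np.maximum(100 + rng.normal(0, 10, (64, 64)), 1e-6)
        state = DiffusionState(image=Image2D(arr))
        params = SradParams(n_iters=1)
        prev = arr.var()
        for _ in range(20):
            state = srad_step(state, params)
            cur = state.image.pixels.var()
            assert cur < prev
            prev = cur

    def test_edge_preserved_while_flat_region_smoothed(self, rng):
        step = np.where(np.arange(64)[None, :] < 32, 100.0, 200.0) * np.ones((64, 1))
        noisy = Image2D(np.maximum(step + rng.normal(0, 10, (64, 64)), 1e-6))
        out = srad(noisy, SradParams(n_iters=20))
        contrast_in = noisy.pixels[:, 33:35].mean() - noisy.pixels[:, 29:31].mean()
        contrast_out = out.pixels[:, 33:35].mean() - out.pixels[:, 29:31].mean()
        assert contrast_out >= 0.8 * contrast_in
        assert out.pixels[:, 40:60].var() <= 0.5 * noisy.pixels[:, 40:60].var()


class TestSrad:
    def test_zero_iterations_is_identity(self, std_phantom):
        img, _ = std_phantom
        out = srad(img, SradParams(n_iters=0))
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_denoising_reduces_mse_to_clean_phantom(self):
        noisy, _ = make_phantom(PhantomSpec(seed=2))
        clean, _ = make_phantom(PhantomSpec(seed=2, noise_sigma=0))
        den = srad(noisy)
        mse_in = ((noisy.pixels - clean.pixels) ** 2).mean()
        mse_out = ((den.pixels - clean.pixels) ** 2).mean()
        assert mse_out < mse_in

    def test_positivity_over_random_phantoms(self):
        for seed in range(10):
            img, _ = make_phantom(PhantomSpec(seed=seed))
            out = srad(img, SradParams(n_iters=10))
            assert out.pixels.min() >= -1e-6

    def test_zero_flux_preserves_total_intensity(self):
        img, _ = make_phantom(PhantomSpec(seed=1))
        out = srad(img, SradParams(n_iters=50))
        drift = abs(out.pixels.sum() - img.pixels.sum()) / img.pixels.sum()
        assert drift <= 0.01

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SradParams(dt=0.5)
        with pytest.raises(ValueError):
            SradParams(n_iters=-1)
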