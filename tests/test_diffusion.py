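import numpy as np
import pytest
from scipy.ndimage import convolve

from shearkad.diffusion import (
    DiffusionParams,
    diffuse,
    diffusion_coefficient,
    diffusion_threshold,
    kernel_gradient_modulus,
    kernel_value,
    local_grayscale_variance,
    perona_malik,
)


class TestKernelValue:
    def test_identity_and_symmetry(self):
        assert kernel_value(7.3, 7.3, 2.0) == 1.0
        assert kernel_value(1.0, 4.0, 2.0) == kernel_value(4.0, 1.0, 2.0)

    def test_one_bandwidth_apart(self):
        assert kernel_value(0.0, 2.0, 2.0) == pytest.approx(np.exp(-0.5))

    def test_invalid_bandwidth(self):
        with pytest.raises(ValueError):
            kernel_value(0.0, 1.0, 0.0)


class TestKernelGradientModulus:
    def test_constant_field_is_zero(self):
        J = np.full((16, 16), 42.0)
        field = kernel_gradient_modulus(J, DiffusionParams(h=1.0))
        np.testing.assert_allclose(field, 0.0)

    def test_saturates_at_sqrt2(self):
        J = np.zeros((8, 8))
        J[::2, :] = 1e9  # rows alternate by a huge step
        field = kernel_gradient_modulus(J, DiffusionParams(h=1.0))
        assert np.all(field <= np.sqrt(2.0) + 1e-12)
        assert field.max() == pytest.approx(np.sqrt(2.0) * np.sqrt(0.5), rel=1e-6)

    def test_single_step_neighbor(self):
        """One neighbor differing by exactly h gives sqrt((2-2e^-1/2)/4)."""
        J = np.zeros((9, 9))
        J[4, 4] = 2.0
        params = DiffusionParams(h=2.0)
        expected = np.sqrt((2 - 2 * np.exp(-0.5)) / 4)
        assert kernel_gradient_modulus(J, params, u=(4, 3)) == pytest.approx(expected)

    def test_matches_brute_force_oracle(self, rng):
        """Vectorized field equals direct per-pixel evaluation with mirrored
        neighbors to 1e-12."""
        J = rng.normal(0, 30, size=(32, 32))
        params = DiffusionParams(h=10.0)
        field = kernel_gradient_modulus(J, params)
        m, n = J.shape
        for i in range(m):
            for j in range(n):
                acc = 0.0
                for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                    ii = min(max(i + di, 0), m - 1)
                    jj = min(max(j + dj, 0), n - 1)
                    f = np.exp(-((J[i, j] - J[ii, jj]) ** 2) / (2 * 10.0**2))
                    acc += 2.0 - 2.0 * f
                assert abs(field[i, j] - np.sqrt(acc / 4)) < 1e-12


class TestDiffusionThreshold:
    def test_constant_field_floored(self):
        assert diffusion_threshold(np.full(10, 3.0), tau_floor=1e-6) == 1e-6

    def test_hand_computed_mad(self):
        assert diffusion_threshold(np.array([1.0, 2.0, 3.0, 4.0, 100.0])) == 1.0

    def test_shift_invariance(self, rng):
        field = rng.uniform(0, 1, 100)
        assert diffusion_threshold(field + 5.0) == pytest.approx(
            diffusion_threshold(field), rel=1e-12
        )


class TestDiffusionCoefficient:
    def test_flat_region_free_diffusion(self):
        assert diffusion_coefficient(0.0, 1.0, 1.0) == 1.0

    def test_known_value(self):
        assert diffusion_coefficient(2.0, 1.0, 1.0) == pytest.approx(np.exp(-1.0))

    def test_edge_limit(self):
        assert diffusion_coefficient(1e6, 1.0, 1.0) == pytest.approx(0.0, abs=1e-300)

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            diffusion_coefficient(1.0, 1.0, 0.0)


class TestLocalVariance:
    def test_constant_image(self):
        v = local_grayscale_variance(np.full((16, 16), 9.0), 3)
        np.testing.assert_allclose(v, 0.0)

    def test_matches_sliding_window_oracle(self, rng):
        J = rng.normal(size=(20, 20))
        v = local_grayscale_variance(J, 3, normalize=False)
        padded = np.pad(J, 1, mode="reflect")
        for i in range(3, 17):
            for j in range(3, 17):
                win = padded[i : i + 3, j : j + 3]
                assert v[i, j] == pytest.approx(win.var(), rel=1e-9)

    def test_translation_equivariance(self, rng):
        J = rng.normal(size=(24, 24))
        v = local_grayscale_variance(J, 5, normalize=False)
        v_shift = local_grayscale_variance(np.roll(J, 3, axis=0), 5, normalize=False)
        np.testing.assert_allclose(np.roll(v, 3, axis=0)[6:-6], v_shift[6:-6], rtol=1e-9)


class TestDiffuse:
    def test_constant_unchanged(self):
        J = np.full((32, 32), 55.0)
        out = diffuse(J, DiffusionParams(h=1.0, n_iterations=5))
        np.testing.assert_allclose(out, 55.0)

    def test_mean_conservation_and_extremum(self, phantom128):
        from shearkad import NoiseSpec, add_gaussian_noise

        noisy = add_gaussian_noise(phantom128, NoiseSpec(sigma=15, seed=0))
        out = diffuse(noisy, DiffusionParams())
        assert abs(out.mean() - noisy.mean()) / abs(noisy.mean()) < 1e-9
        assert out.min() >= noisy.min() - 1e-9
        assert out.max() <= noisy.max() + 1e-9

    def test_free_diffusion_limit(self):
        """With huge bandwidth and a fixed tau floor the scheme reduces to
        the linear 5-point heat iteration."""
        J = np.zeros((33, 33))
        J[16, 16] = 100.0
        out = diffuse(J, DiffusionParams(h=1e8, tau_floor=1.0, n_iterations=8, dt=0.2))
        g = 0.2 / 4
        kernel = np.array([[0, g, 0], [g, 1 - 4 * g, g], [0, g, 0]])
        ref = J.copy()
        for _ in range(8):
            ref = convolve(ref, kernel, mode="mirror")
        assert np.max(np.abs(out - ref)) < 1e-9

    def test_edge_preserved_while_noise_shrinks(self):
        """On a noisy 50/150 step edge, within-region variance falls and the
        50%-crossing stays put."""
        clean = np.where(np.arange(64)[None, :] < 32, 50.0, 150.0) * np.ones((64, 1))
        noisy = clean + np.random.default_rng(1).normal(0, 10, (64, 64))
        out = diffuse(noisy, DiffusionParams())
        assert out[:, :24].var() < noisy[:, :24].var()
        assert out[:, 40:].var() < noisy[:, 40:].var()
        crossings = np.argmax(out >= 100.0, axis=1)
        assert np.all(np.abs(crossings - 32) <= 1)

    def test_total_variation_monotone_on_slices(self):
        rng = np.random.default_rng(2)
        J = np.cumsum(rng.normal(0, 5, (48, 48)), axis=1) + rng.normal(0, 10, (48, 48))
        prev = np.sum(np.abs(np.diff(J, axis=1)))
        for _ in range(5):
            J = diffuse(J, DiffusionParams(n_iterations=1))
            tv = np.sum(np.abs(np.diff(J, axis=1)))
            assert tv <= prev + 1e-9
            prev = tv

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            DiffusionParams(dt=0.5)
        with pytest.raises(ValueError):
            DiffusionParams(window=4)
        with pytest.raises(ValueError):
            DiffusionParams(neighborhood=6)


class TestPeronaMalik:
    def test_constant_unchanged(self):
        J = np.full((16, 16), 7.0)
        np.testing.assert_allclose(perona_malik(J, n_iterations=3), 7.0)

    def test_reduces_noise_variance(self):
        rng = np.random.default_rng(0)
        noisy = np.full((64, 64), 100.0) + rng.normal(0, 10, (64, 64))
        out = perona_malik(noisy, n_iterations=10)
        assert out.var() < noisy.var()
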