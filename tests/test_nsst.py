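import numpy as np
import pytest

from shearkad import build_filterbank, forward, inverse
from shearkad.nsst import SubbandSet, build_radial_bank


class TestFilterBank:
    def test_partition_of_unity(self, bank64):
        assert bank64.partition_of_unity_error() < 1e-6

    def test_window_counts(self, bank64):
        counts = [len(row) for row in bank64.high_windows]
        assert counts == [8, 8, 4]
        assert bank64.low_window.shape == (64, 64)

    def test_cone_mirror_symmetry(self, bank64):
        """The directional window for shear index k and its cone-mirrored
        counterpart are reflections across the frequency diagonal."""
        for r, n_dir in enumerate(bank64.directions_per_scale, start=1):
            for d in range(n_dir):
                mirrored = (n_dir // 2 - d) % n_dir
                a = bank64.high_windows[r - 1][d]
                b = bank64.high_windows[r - 1][mirrored]
                assert np.max(np.abs(a.T - b)) < 1e-10

    def test_invalid_directions_rejected(self):
        with pytest.raises(ValueError):
            build_filterbank((64, 64), 2, (8, 3))
        with pytest.raises(ValueError):
            build_filterbank((64, 64), 2, (8, 1))

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            build_filterbank((16, 16), 3, (8, 8, 4))

    @pytest.mark.parametrize(
        "shape,n_scales,dirs",
        [((64, 64), 2, (8, 4)), ((64, 96), 3, (8, 8, 4)), ((128, 128), 4, (16, 8, 8, 4))],
    )
    def test_partition_for_other_configs(self, shape, n_scales, dirs):
        bank = build_filterbank(shape, n_scales, dirs)
        assert bank.partition_of_unity_error() < 1e-6


class TestForward:
    def test_constant_image(self, bank64):
        coeffs = forward(np.full((64, 64), 200.0), bank64)
        for _, _, band in coeffs.bands():
            assert np.max(np.abs(band)) < 1e-8 * 200.0
        recon = inverse(SubbandSet(coeffs.low, [[np.zeros((64, 64))] * n for n in (8, 8, 4)]), bank64)
        np.testing.assert_allclose(recon, 200.0, atol=1e-9)

    def test_linearity(self, bank64, rng):
        x = rng.normal(size=(64, 64))
        y = rng.normal(size=(64, 64))
        cx, cy = forward(x, bank64), forward(y, bank64)
        cxy = forward(2.0 * x - 0.5 * y, bank64)
        for (_, _, a), (_, _, b), (_, _, ab) in zip(cx.bands(), cy.bands(), cxy.bands()):
            np.testing.assert_allclose(2.0 * a - 0.5 * b, ab, atol=1e-9)
        np.testing.assert_allclose(2.0 * cx.low - 0.5 * cy.low, cxy.low, atol=1e-9)

    def test_tight_frame_energy(self, bank64):
        """Parseval: subband energies sum to the input energy (partition of
        unity makes the analysis a tight frame with frame constant 1)."""
        impulse = np.zeros((64, 64))
        impulse[10, 20] = 1.0
        coeffs = forward(impulse, bank64)
        energy = sum(np.sum(b**2) for _, _, b in coeffs.bands()) + np.sum(coeffs.low**2)
        assert abs(energy - 1.0) < 1e-9

    def test_shape_mismatch_rejected(self, bank64):
        with pytest.raises(ValueError):
            forward(np.zeros((32, 32)), bank64)

    def test_oriented_edge_direction_selectivity(self, bank64):
        """A straight oriented edge concentrates most high-band energy in the
        few directional subbands aligned with its spectrum."""
        img = np.zeros((64, 64))
        img[32:, :] = 100.0  # horizontal edge; spectrum lives on the f1 axis
        coeffs = forward(img, bank64)
        total = 0.0
        aligned = 0.0
        for r, d, band in coeffs.bands():
            e = np.sum(band**2)
            total += e
            n_dir = bank64.directions_per_scale[r - 1]
            if d in (0, 1, n_dir - 1):
                aligned += e
        assert aligned / total > 0.5


class TestInverse:
    @pytest.mark.parametrize("shape", [(64, 64), (128, 128)])
    def test_round_trip_random(self, shape, rng):
        bank = build_filterbank(shape, 3, (8, 8, 4))
        x = rng.normal(0, 50, size=shape)
        err = np.max(np.abs(inverse(forward(x, bank), bank) - x))
        assert err < 1e-6

    def test_round_trip_phantom(self, phantom128):
        bank = build_filterbank((128, 128), 3, (8, 8, 4))
        err = np.max(np.abs(inverse(forward(phantom128, bank), bank) - phantom128))
        assert err < 1e-6

    def test_zero_coefficients_give_zero(self, bank64):
        zeros = SubbandSet(np.zeros((64, 64)), [[np.zeros((64, 64))] * n for n in (8, 8, 4)])
        np.testing.assert_array_equal(inverse(zeros, bank64), np.zeros((64, 64)))

    def test_incompatible_bank_rejected(self, bank64, rng):
        other = build_filterbank((64, 64), 2, (8, 4))
        coeffs = forward(rng.normal(size=(64, 64)), bank64)
        with pytest.raises(ValueError):
            inverse(coeffs, other)


class TestRadialBank:
    def test_partition_and_round_trip(self, rng):
        bands, low = build_radial_bank((64, 64), 3)
        total = low**2 + sum(b**2 for b in bands)
        assert np.max(np.abs(total - 1.0)) < 1e-12
        x = rng.normal(size=(64, 64))
        spec = np.fft.fft2(x)
        acc = np.fft.fft2(np.fft.ifft2(spec * low).real) * low
        for b in bands:
            acc = acc + np.fft.fft2(np.fft.ifft2(spec * b).real) * b
        assert np.max(np.abs(np.fft.ifft2(acc).real - x)) < 1e-10
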