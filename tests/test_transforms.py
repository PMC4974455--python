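"""Fourier operators, hypercomplex magnitudes and the point-spread function,
checked against brute-force DFT loops on small instances."""

import numpy as np
import pytest

from rnoise.datamodel import Role, SamplingSchedule, SparseDataset
from rnoise.transforms import (
    Spectrum,
    _hyper_fft,
    back_calculate,
    hyper_magnitude,
    point_spread_function,
    zero_fill_transform,
)


def brute_dft(values: np.ndarray, positions: np.ndarray, n_grid: int) -> np.ndarray:
    """O(N^2) unitary DFT of zero-filled sparse data; the oracle."""
    out = np.zeros(n_grid, dtype=complex)
    for k in range(n_grid):
        acc = 0.0 + 0.0j
        for v, t in zip(values, positions):
            acc += v * np.exp(-2j * np.pi * k * t / n_grid)
        out[k] = acc / np.sqrt(n_grid)
    return out


def _dataset(n_grid, flat, z):
    sched = SamplingSchedule((n_grid,), np.asarray(flat))
    return SparseDataset.from_complex(sched, np.asarray(z, complex))


@pytest.mark.parametrize(
    "components, expected",
    [((3.0, 4.0), 5.0), ((0.0, 0.0, 0.0, 0.0), 0.0), ((1.0, 1.0, 1.0, 1.0), 2.0)],
)
def test_hyper_magnitude_values(components, expected):
    assert hyper_magnitude(np.asarray(components)) == pytest.approx(expected)


def test_hyper_magnitude_complex_is_modulus():
    z = np.array([3 + 4j, 1j])
    np.testing.assert_allclose(hyper_magnitude(z), [5.0, 1.0])


class TestZeroFillTransform:
    def test_delta_gives_flat_spectrum(self):
        n = 16
        spec = zero_fill_transform(_dataset(n, [0], [1.0]))
        np.testing.assert_allclose(np.abs(spec.data), 1 / np.sqrt(n), atol=1e-12)

    def test_full_sinusoid_gives_single_line(self):
        n = 32
        k0 = 5
        z = np.exp(2j * np.pi * k0 * np.arange(n) / n)
        spec = zero_fill_transform(_dataset(n, np.arange(n), z))
        mags = np.abs(spec.data)
        assert np.argmax(mags) == k0
        assert np.count_nonzero(mags > 1e-10) == 1

    def test_all_zero_values_give_zero_spectrum(self):
        spec = zero_fill_transform(_dataset(8, [1, 4], [0.0, 0.0]))
        assert np.all(spec.data == 0)

    def test_matches_brute_force_dft(self):
        rng = np.random.default_rng(7)
        n = 24
        flat = np.sort(rng.choice(n, 9, replace=False))
        z = rng.normal(size=9) + 1j * rng.normal(size=9)
        spec = zero_fill_transform(_dataset(n, flat, z))
        np.testing.assert_allclose(spec.data, brute_dft(z, flat, n), atol=1e-10)

    def test_parseval(self):
        rng = np.random.default_rng(8)
        n = 64
        z = rng.normal(size=n) + 1j * rng.normal(size=n)
        spec = zero_fill_transform(_dataset(n, np.arange(n), z))
        assert np.sum(np.abs(spec.data) ** 2) == pytest.approx(
            np.sum(np.abs(z) ** 2), rel=1e-10
        )

    def test_linearity(self):
        rng = np.random.default_rng(9)
        n = 32
        flat = np.sort(rng.choice(n, 12, replace=False))
        x = rng.normal(size=12) + 1j * rng.normal(size=12)
        y = rng.normal(size=12) + 1j * rng.normal(size=12)
        a, b = 2.5 - 1j, -0.7 + 0.2j
        lhs = zero_fill_transform(_dataset(n, flat, a * x + b * y)).data
        rhs = a * zero_fill_transform(_dataset(n, flat, x)).data + b * (
            zero_fill_transform(_dataset(n, flat, y)).data
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)


class TestBackCalculate:
    def test_zero_spectrum_gives_zeros(self):
        model = Spectrum((16,), np.zeros(16, complex))
        out = back_calculate(model, np.array([0, 3, 9]))
        assert np.all(out == 0)

    def test_round_trip_identity_on_full_grid(self):
        rng = np.random.default_rng(10)
        n = 40
        z = rng.normal(size=n) + 1j * rng.normal(size=n)
        spec = zero_fill_transform(_dataset(n, np.arange(n), z))
        out = back_calculate(spec, np.arange(n))
        np.testing.assert_allclose(out[:, 0] + 1j * out[:, 1], z, atol=1e-10)

    def test_single_component_is_sampled_exponential(self):
        n = 16
        k0 = 3
        data = np.zeros(n, complex)
        data[k0] = 1.0
        pos = np.array([0, 2, 7, 15])
        out = back_calculate(Spectrum((n,), data), pos)
        expected = np.exp(2j * np.pi * k0 * pos / n) / np.sqrt(n)
        np.testing.assert_allclose(out[:, 0] + 1j * out[:, 1], expected, atol=1e-12)

    def test_out_of_grid_position_rejected(self):
        model = Spectrum((8,), np.zeros(8, complex))
        with pytest.raises(IndexError):
            back_calculate(model, np.array([8]))


class TestPointSpreadFunction:
    def test_full_sampling_is_delta(self):
        sched = SamplingSchedule((16,), np.arange(16))
        psf = point_spread_function(sched)
        assert abs(psf.data[0]) == pytest.approx(1.0)
        assert np.all(np.abs(psf.data[1:]) < 1e-12)

    def test_even_comb_has_single_ghost(self):
        sched = SamplingSchedule((16,), np.arange(0, 16, 2))
        psf = point_spread_function(sched)
        mags = np.abs(psf.data)
        nonzero = np.nonzero(mags > 1e-12)[0]
        assert nonzero.tolist() == [0, 8]

    def test_peak_normalized(self):
        rng = np.random.default_rng(11)
        sched = SamplingSchedule((64,), np.sort(rng.choice(64, 17, replace=False)))
        psf = point_spread_function(sched)
        assert np.max(np.abs(psf.data)) == pytest.approx(1.0)


class TestDirtySpectrumPsfEquivalence:
    def test_psf_subtraction_equals_time_domain_removal(self):
        """Removing a recovered component from the dirty spectrum via the
        shifted PSF is the same as removing it from the time domain first."""
        rng = np.random.default_rng(12)
        n = 48
        flat = np.sort(rng.choice(n, 20, replace=False))
        z = rng.normal(size=20) + 1j * rng.normal(size=20)
        ds = _dataset(n, flat, z)
        dirty = zero_fill_transform(ds).data
        k0, amp = 11, 1.3 - 0.4j
        psf = point_spread_function(ds.schedule).data
        # the PSF response of spectrum amplitude `amp` at bin k0, accounting
        # for the dirty-peak attenuation n_meas / n_grid
        response = amp * (len(flat) / n) * np.roll(psf, k0)
        z_removed = z - amp * np.exp(2j * np.pi * k0 * flat / n) / np.sqrt(n)
        dirty_removed = zero_fill_transform(_dataset(n, flat, z_removed)).data
        np.testing.assert_allclose(dirty - response, dirty_removed, atol=1e-10)


class TestHypercomplex:
    def test_round_trip_and_parseval(self):
        rng = np.random.default_rng(13)
        a = rng.normal(size=(6, 5, 2, 2))
        fa = _hyper_fft(a)
        assert np.sum(fa**2) == pytest.approx(np.sum(a**2), rel=1e-10)
        np.testing.assert_allclose(_hyper_fft(fa, inverse=True), a, atol=1e-12)

    def test_back_calculate_matches_per_axis_oracle(self):
        """2-D hypercomplex transform agrees with looped per-axis DFTs."""
        rng = np.random.default_rng(14)
        n1, n2 = 4, 6
        grid = rng.normal(size=(n1, n2, 2, 2))
        # oracle: axis-wise complex DFT loops on the quadrature pairs,
        # forward along axis 0 on (RR + i*IR, RI + i*II)
        za = grid[:, :, 0, :] + 1j * grid[:, :, 1, :]  # axis-0 quadrature pair
        fa = np.zeros_like(za)
        for k in range(n1):
            for t in range(n1):
                fa[k] += za[t] * np.exp(-2j * np.pi * k * t / n1)
        fa /= np.sqrt(n1)
        inter = np.stack([fa.real, fa.imag], axis=2)  # (n1, n2, 2, 2)
        zb = inter[:, :, :, 0] + 1j * inter[:, :, :, 1]
        fb = np.zeros_like(zb)
        for k in range(n2):
            for t in range(n2):
                fb[:, k] += zb[:, t] * np.exp(-2j * np.pi * k * t / n2)
        fb /= np.sqrt(n2)
        oracle = np.stack([fb.real, fb.imag], axis=3)
        np.testing.assert_allclose(_hyper_fft(grid), oracle, atol=1e-10)
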