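"""R-factors, noise normalization, aggregation and spectrum RMSD."""

import numpy as np
import pytest

from rnoise.datamodel import split_measurements
from rnoise.rfactor import (
    aggregate_quality,
    r_factor,
    r_noise,
    score_split,
    spectrum_rmsd,
)
from rnoise.synth import PlaneParams, SimulationParams, simulate_1d, simulate_plane
from rnoise.transforms import Spectrum, hyper_magnitude, zero_fill_transform


class TestRFactor:
    def test_zero_model_scores_100_percent(self):
        obs = np.array([[1.0, 2.0], [0.5, -1.0]])
        assert r_factor(obs, np.zeros_like(obs)) == 1.0

    def test_perfect_model_scores_zero(self):
        obs = np.array([[1.0, 2.0], [0.5, -1.0]])
        assert r_factor(obs, obs) == 0.0

    def test_orthogonal_unit_vectors(self):
        assert r_factor(np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]])) == pytest.approx(
            np.sqrt(2), rel=1e-12
        )

    def test_all_zero_observations_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            r_factor(np.zeros((3, 2)), np.ones((3, 2)))

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        obs = rng.normal(size=(20, 2))
        calc = rng.normal(size=(20, 2))
        assert r_factor(7.3 * obs, 7.3 * calc) == pytest.approx(
            r_factor(obs, calc), rel=1e-12
        )

    def test_triangle_bound(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            obs = rng.normal(size=(15, 2))
            calc = rng.normal(size=(15, 2))
            bound = 1.0 + np.sum(hyper_magnitude(calc)) / np.sum(hyper_magnitude(obs))
            assert r_factor(obs, calc) <= bound + 1e-12


class TestRNoise:
    def test_perfect_model_scores_zero(self):
        obs = np.array([[1.0, 2.0]])
        assert r_noise(obs, obs, np.array([[1.0, 0.0]])) == 0.0

    def test_hand_computed_ratio(self):
        # residual magnitude 2 over noise magnitude 1
        assert r_noise(
            np.array([[2.0, 0.0]]), np.array([[0.0, 0.0]]), np.array([[1.0, 0.0]])
        ) == pytest.approx(2.0)

    def test_zero_noise_reference_rejected(self):
        with pytest.raises(ValueError, match="noise"):
            r_noise(np.ones((2, 2)), np.zeros((2, 2)), np.zeros((3, 2)))

    def test_pure_noise_with_zero_model_is_near_unity(self):
        """Zero model on noise drawn from the reference distribution -> ~1."""
        rng = np.random.default_rng(3)
        n = 4000
        obs = rng.normal(0, 0.5, size=(n, 2))
        ref = rng.normal(0, 0.5, size=(n, 2))
        val = r_noise(obs, np.zeros_like(obs), ref)
        assert abs(val - 1.0) < 3 / np.sqrt(n)

    def test_scaling_behaviour(self):
        """Linear in residual scale, inverse in noise-reference scale."""
        rng = np.random.default_rng(4)
        obs = rng.normal(size=(30, 2))
        ref = rng.normal(size=(25, 2))
        base = r_noise(obs, np.zeros_like(obs), ref)
        assert r_noise(3.0 * obs, np.zeros_like(obs), ref) == pytest.approx(3 * base)
        assert r_noise(obs, np.zeros_like(obs), 2.0 * ref) == pytest.approx(base / 2)

    def test_mean_normalization_balances_set_sizes(self):
        """Doubling the noise set by repetition leaves the ratio unchanged."""
        rng = np.random.default_rng(5)
        obs = rng.normal(size=(10, 2))
        ref = rng.normal(size=(8, 2))
        assert r_noise(obs, 0 * obs, np.vstack([ref, ref])) == pytest.approx(
            r_noise(obs, 0 * obs, ref), rel=1e-12
        )


class TestScoreSplit:
    def test_zero_model_on_noise_plane(self):
        plane, _ = simulate_plane(PlaneParams(seed=21), "noise")
        ref, _ = simulate_plane(PlaneParams(seed=22), "noise")
        split = split_measurements(plane, 0.1, seed=3)
        model = Spectrum(plane.schedule.grid_shape, np.zeros(plane.schedule.grid_shape + (2, 2)))
        rep = score_split(model, split, ref)
        assert rep.r_work == 1.0 and rep.r_free == 1.0
        n_w, n_f = rep.n_work, rep.n_free
        assert abs(rep.rnoise_work - 1) < 3 / np.sqrt(n_w)
        assert abs(rep.rnoise_free - 1) < 3 / np.sqrt(n_f)

    def test_exact_model_scores_zero_everywhere(self):
        sim = simulate_1d(SimulationParams(seed=6, noise_sigma=0.0))
        split = split_measurements(sim.sparse, 0.2, seed=1)
        noisy_ref = simulate_1d(SimulationParams(seed=7)).noise_ref
        rep = score_split(sim.truth, split, noisy_ref)
        assert rep.r_work < 1e-10 and rep.r_free < 1e-10
        assert rep.rnoise_work < 1e-10 and rep.rnoise_free < 1e-10

    def test_noise_normalization_removes_signal_content_dependence(self):
        """Strong vs weak planes scored with the true model: conventional
        R_work swings by more than 5x while R_noise_work stays near 1."""
        params = PlaneParams(seed=23)
        ref, _ = simulate_plane(PlaneParams(seed=24), "noise")
        r_works, rnoises = {}, {}
        for kind in ("strong", "weak"):
            ds, truth = simulate_plane(params, kind)
            split = split_measurements(ds, 0.1, seed=5)
            rep = score_split(truth, split, ref)
            r_works[kind] = rep.r_work
            rnoises[kind] = rep.rnoise_work
        assert r_works["weak"] / r_works["strong"] > 5
        for val in rnoises.values():
            assert 0.8 < val < 1.2

    def test_true_signal_model_on_noisy_data_near_unity(self):
        sim = simulate_1d(SimulationParams(seed=8))
        split = split_measurements(sim.sparse, 0.2, seed=2)
        rep = score_split(sim.truth, split, sim.noise_ref)
        assert abs(rep.rnoise_work - 1) < 0.1
        assert abs(rep.rnoise_free - 1) < 0.25  # only 61 free points


class TestAggregate:
    def _report(self, **kw):
        from rnoise.rfactor import RFactorReport

        base = dict(
            r_work=0.1, r_free=0.2, rnoise_work=1.0, rnoise_free=1.0,
            control_name="t", control_value=0.0, n_work=10, n_free=2,
        )
        base.update(kw)
        return RFactorReport(**base)

    def test_single_report_has_zero_sd(self):
        s = aggregate_quality([self._report()])
        assert s.n == 1
        assert s.rnoise_free_mean == 1.0 and s.rnoise_free_sd == 0.0

    def test_hand_computed_mean_and_sd(self):
        s = aggregate_quality(
            [self._report(rnoise_free=1.0), self._report(rnoise_free=1.2)]
        )
        assert s.rnoise_free_mean == pytest.approx(1.1)
        assert s.rnoise_free_sd == pytest.approx(np.sqrt(0.02), rel=1e-10)

    def test_identical_reports_have_zero_sd(self):
        s = aggregate_quality([self._report()] * 4)
        assert s.r_work_sd == 0.0

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            aggregate_quality([])


class TestSpectrumRmsd:
    def test_identical_spectra(self):
        s = Spectrum((8,), np.arange(8, dtype=complex))
        assert spectrum_rmsd(s, s) == 0.0

    def test_constant_offset(self):
        a = Spectrum((8,), np.zeros(8, complex))
        b = Spectrum((8,), np.full(8, 3 - 4j))
        assert spectrum_rmsd(a, b) == pytest.approx(5.0)

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=8) + 1j * rng.normal(size=8)
        y = rng.normal(size=8) + 1j * rng.normal(size=8)
        acc = sum(abs(xi - yi) ** 2 for xi, yi in zip(x, y))
        expected = np.sqrt(acc / 8)
        assert spectrum_rmsd(Spectrum((8,), x), Spectrum((8,), y)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            spectrum_rmsd(Spectrum((8,), np.zeros(8, complex)), Spectrum((4,), np.zeros(4, complex)))
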