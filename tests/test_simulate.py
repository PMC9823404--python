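"""Synthetic voltammogram generator: shape, linearity, overlap, determinism."""

import numpy as np
import pytest

import voltacal as vc
from voltacal.simulate import CONC_MAX, CONC_MIN, clean_current


def _sample(para=0.0, diclo=0.0, nap=0.0, asp=0.0, interferents=(0.0, 0.0, 0.0)):
    return vc.MixtureSample(
        analyte_conc=(para, diclo, nap, asp), interferent_conc=interferents
    )


ZERO_NOISE = vc.NoiseModel(baseline_intercept=0.0, baseline_slope=0.0, noise_sd=0.0)


class TestSimulateVoltammogram:
    def test_no_sources_gives_zero_trace(self, peaks, grid):
        v = vc.simulate_voltammogram(_sample(), peaks, grid, ZERO_NOISE)
        assert np.all(v.current == 0.0)

    def test_peak_current_linear_in_concentration(self, peaks, grid):
        v1 = vc.simulate_voltammogram(_sample(para=10), peaks, grid, ZERO_NOISE)
        v2 = vc.simulate_voltammogram(_sample(para=20), peaks, grid, ZERO_NOISE)
        assert np.allclose(v2.current, 2.0 * v1.current)

    def test_paracetamol_peak_at_characteristic_potential(self, peaks, grid):
        # independent closed-form oracle: evaluate the Gaussian sum directly
        v = vc.simulate_voltammogram(_sample(para=80), peaks, grid, ZERO_NOISE)
        e = grid.potentials
        expected = sum(
            p.sensitivity * 80 * np.exp(-((e - p.center) ** 2) / (2 * p.width**2))
            for p in peaks
            if p.owner == "paracetamol"
        )
        assert np.allclose(v.current, expected)
        assert np.argmax(v.current) == np.argmin(np.abs(e - 0.446))

    def test_additivity_of_single_analyte_traces(self, peaks, grid):
        base = vc.NoiseModel(noise_sd=0.0)  # shared nonzero baseline
        mix = vc.simulate_voltammogram(
            _sample(10, 20, 30, 40), peaks, grid, base
        ).current
        singles = [
            vc.simulate_voltammogram(s, peaks, grid, base).current
            for s in (_sample(para=10), _sample(diclo=20), _sample(nap=30), _sample(asp=40))
        ]
        baseline = vc.simulate_voltammogram(_sample(), peaks, grid, base).current
        assert np.allclose(mix, sum(singles) - 3 * baseline, atol=1e-12)

    def test_peak_height_proportionality_high_precision(self, peaks, grid):
        for owner, idx in zip(vc.ANALYTES, range(4)):
            center = next(p.center for p in peaks if p.owner == owner)
            i_peak = np.argmin(np.abs(grid.potentials - center))
            conc = np.zeros(4)
            conc[idx] = 7.0
            h1 = clean_current(
                vc.MixtureSample(tuple(conc), (0, 0, 0)), peaks, grid, ZERO_NOISE
            )[i_peak]
            conc[idx] = 21.0
            h3 = clean_current(
                vc.MixtureSample(tuple(conc), (0, 0, 0)), peaks, grid, ZERO_NOISE
            )[i_peak]
            assert abs(h3 / h1 - 3.0) < 1e-9

    def test_naproxen_aspirin_traces_nearly_collinear(self, peaks, grid):
        nap = vc.simulate_voltammogram(_sample(nap=40), peaks, grid, ZERO_NOISE)
        asp = vc.simulate_voltammogram(_sample(asp=40), peaks, grid, ZERO_NOISE)
        r = np.corrcoef(nap.current, asp.current)[0, 1]
        assert r > 0.9

    def test_seed_determinism(self, peaks, grid):
        noise = vc.NoiseModel(noise_sd=0.5, seed=7)
        v1 = vc.simulate_voltammogram(_sample(para=5), peaks, grid, noise)
        v2 = vc.simulate_voltammogram(_sample(para=5), peaks, grid, noise)
        assert np.array_equal(v1.current, v2.current)

    def test_unknown_owner_rejected(self, grid):
        bad = [vc.PeakSpec(0.5, 0.05, 0.1, "caffeine")] + vc.default_peak_table()
        with pytest.raises(ValueError, match="caffeine"):
            vc.simulate_voltammogram(_sample(para=1), bad, grid, ZERO_NOISE)

    def test_missing_analyte_peak_rejected(self, grid):
        only_para = [vc.PeakSpec(0.446, 0.05, 0.1, "paracetamol")]
        with pytest.raises(ValueError, match="misses"):
            vc.simulate_voltammogram(_sample(para=1), only_para, grid, ZERO_NOISE)

    def test_unresolved_noise_rejected(self, peaks, grid):
        with pytest.raises(ValueError, match="unresolved"):
            vc.simulate_voltammogram(_sample(para=1), peaks, grid, vc.NoiseModel())


class TestTrainingSet:
    def test_factorial_design_gives_81_columns(self, peaks, grid):
        ranges = [vc.FactorRange(a, CONC_MIN, CONC_MAX) for a in vc.ANALYTES]
        design = vc.to_actual(vc.full_factorial(3, 4), ranges)
        v, c = vc.generate_training_set(design, peaks, grid, vc.NoiseModel(seed=0))
        assert v.shape == (grid.n_points, 81)
        assert c.shape == (4, 81)
        # column order matches design row order
        assert np.array_equal(c.T, design.actual)

    def test_toy_design_gives_two_columns(self, peaks, grid):
        toy = np.array([[0.5, 0.5, 0.5, 0.5], [80.0, 0.5, 0.5, 0.5]])
        v, c = vc.generate_training_set(toy, peaks, grid, vc.NoiseModel(seed=0))
        assert v.shape[1] == 2 and c.shape[1] == 2

    def test_identical_seeds_bit_identical(self, peaks, grid):
        toy = np.array([[1.0, 2.0, 3.0, 4.0]])
        out1 = vc.generate_training_set(toy, peaks, grid, vc.NoiseModel(seed=3))
        out2 = vc.generate_training_set(toy, peaks, grid, vc.NoiseModel(seed=3))
        assert np.array_equal(out1[0], out2[0])

    def test_out_of_range_design_rejected(self, peaks, grid):
        with pytest.raises(ValueError, match="0.5, 80"):
            vc.generate_training_set(
                np.array([[0.0, 1, 1, 1]]), peaks, grid, vc.NoiseModel(seed=0)
            )

    def test_auto_noise_is_one_percent_of_clean_max(self, peaks, grid):
        from voltacal.simulate import resolve_noise

        ranges = [vc.FactorRange(a, CONC_MIN, CONC_MAX) for a in vc.ANALYTES]
        design = vc.to_actual(vc.full_factorial(3, 4), ranges)
        resolved = resolve_noise(design, peaks, grid, vc.NoiseModel())
        clean_cols = [
            clean_current(vc.MixtureSample(tuple(row)), peaks, grid, resolved)
            for row in design.actual
        ]
        assert resolved.noise_sd == pytest.approx(0.01 * np.max(clean_cols))


class TestRandomTestSet:
    def test_requested_number_of_columns(self, peaks, grid):
        v, c = vc.generate_random_test_set(
            10, 5, peaks, grid, vc.NoiseModel(noise_sd=0.1)
        )
        assert v.shape == (grid.n_points, 10) and c.shape == (4, 10)

    def test_reproducible_under_seed(self, peaks, grid):
        noise = vc.NoiseModel(noise_sd=0.1, seed=2)
        a = vc.generate_random_test_set(1, 9, peaks, grid, noise)
        b = vc.generate_random_test_set(1, 9, peaks, grid, noise)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_concentration_sampler_mean(self, peaks, grid):
        # law of large numbers: uniform on [0.5, 80] has mean 40.25
        _, c = vc.generate_random_test_set(
            40_000, 11, peaks, vc.PotentialGrid(n_points=4), vc.NoiseModel(noise_sd=0.0)
        )
        assert np.all(np.abs(c.mean(axis=1) / 40.25 - 1.0) < 0.01)
        assert c.min() >= CONC_MIN and c.max() <= CONC_MAX

    def test_nonpositive_n_rejected(self, peaks, grid):
        with pytest.raises(ValueError):
            vc.generate_random_test_set(0, 1, peaks, grid, vc.NoiseModel(noise_sd=0))
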