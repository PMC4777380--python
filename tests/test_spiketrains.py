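"""Poisson spike-train generation and the thinned-correlation construction."""

import numpy as np
import pytest
from scipy import stats as sps

from stdpop import (
    InputEnsemble,
    SpikeTrain,
    generate_correlated_group,
    generate_homogeneous_poisson,
    measure_pairwise_correlation,
)


class TestHomogeneousPoisson:
    def test_zero_rate_gives_empty_train(self):
        tr = generate_homogeneous_poisson(0.0, 1e6, seed=0)
        assert tr.n_spikes == 0

    def test_count_matches_poisson_mean(self):
        tr = generate_homogeneous_poisson(10.0, 1e6, seed=1)
        # Poisson(10^4): 5 sigma band
        assert abs(tr.n_spikes - 10_000) < 5 * 100

    def test_intervals_are_exponential(self):
        tr = generate_homogeneous_poisson(10.0, 1e6, seed=2)
        isi = np.diff(tr.times)
        _, p = sps.kstest(isi, "expon", args=(0, 100.0))
        assert p > 0.01

    def test_times_sorted_within_duration(self):
        tr = generate_homogeneous_poisson(50.0, 1e4, seed=3)
        assert np.all(np.diff(tr.times) > 0)
        assert tr.times[0] >= 0 and tr.times[-1] < tr.duration

    @pytest.mark.parametrize("rate,duration", [(-1.0, 100.0), (10.0, 0.0)])
    def test_invalid_parameters_raise(self, rate, duration):
        with pytest.raises(ValueError):
            generate_homogeneous_poisson(rate, duration)


class TestCorrelatedGroup:
    def test_c_equal_one_gives_identical_trains(self):
        trains = generate_correlated_group(5, 10.0, 1.0, 1e5, seed=0)
        for tr in trains[1:]:
            np.testing.assert_array_equal(tr.times, trains[0].times)

    def test_c_zero_gives_independent_trains(self):
        trains = generate_correlated_group(20, 10.0, 0.0, 1e6, seed=1)
        corr, se = measure_pairwise_correlation(trains)
        assert abs(corr) < 3 * se + 1e-3

    @pytest.mark.parametrize("c", [0.1, 0.2, 0.5, 1.0])
    def test_rates_match_nominal(self, c):
        duration = 1e6
        trains = generate_correlated_group(30, 10.0, c, duration, seed=int(c * 100))
        n = np.array([t.n_spikes for t in trains])
        # per-train count is Poisson(1e4): 3 SE band on the group mean,
        # allowing for the shared-parent covariance between trains
        expect = 10.0 * duration / 1000.0
        var_mean = expect / n.size + c * expect * (1 - 1 / n.size)
        assert abs(n.mean() - expect) < 3 * np.sqrt(var_mean) + 3 * np.sqrt(expect)

    def test_pairwise_correlation_matches_c(self):
        # closed form: thinning a common parent gives count correlation c
        trains = generate_correlated_group(100, 10.0, 0.5, 1e6, seed=7)
        corr, se = measure_pairwise_correlation(trains)
        assert abs(corr - 0.5) < max(3 * se, 0.01)

    @pytest.mark.parametrize("bin_width", [1.0, 5.0, 20.0])
    def test_correlation_is_bin_width_independent(self, bin_width):
        trains = generate_correlated_group(60, 10.0, 0.3, 5e5, seed=9)
        corr, se = measure_pairwise_correlation(trains, bin_width=bin_width)
        assert abs(corr - 0.3) < max(3 * se, 0.02)

    def test_invalid_c_raises(self):
        with pytest.raises(ValueError):
            generate_correlated_group(5, 10.0, 1.5, 1e4)


class TestMeasurePairwiseCorrelation:
    def test_identical_trains_give_unity(self):
        tr = generate_homogeneous_poisson(10.0, 1e5, seed=4)
        corr, _ = measure_pairwise_correlation([tr, tr])
        assert corr == pytest.approx(1.0)

    def test_fewer_than_two_trains_raises(self):
        tr = generate_homogeneous_poisson(10.0, 1e4, seed=5)
        with pytest.raises(ValueError):
            measure_pairwise_correlation([tr])


class TestInputEnsemble:
    def test_generation_is_seed_deterministic(self):
        a = InputEnsemble.generate(1e4, n_ex=20, n_in=5, correlation=0.2, seed=42)
        b = InputEnsemble.generate(1e4, n_ex=20, n_in=5, correlation=0.2, seed=42)
        for ta, tb in zip(a.excitatory_trains, b.excitatory_trains):
            np.testing.assert_array_equal(ta.times, tb.times)

    def test_different_seeds_differ(self):
        a = InputEnsemble.generate(1e4, n_ex=5, n_in=2, seed=1)
        b = InputEnsemble.generate(1e4, n_ex=5, n_in=2, seed=2)
        assert not np.array_equal(
            a.excitatory_trains[0].times, b.excitatory_trains[0].times
        )

    def test_mask_marks_correlated_fraction(self):
        ens = InputEnsemble.generate(
            1e4, n_ex=100, n_in=10, correlation=0.2, frac_correlated=0.5, seed=3
        )
        assert ens.correlated_mask.sum() == 50

    def test_csv_roundtrip(self, tmp_path):
        ens = InputEnsemble.generate(1e4, n_ex=8, n_in=3, correlation=0.5, seed=6)
        path = tmp_path / "spikes.csv"
        ens.to_csv(path)
        back = InputEnsemble.from_csv(path)
        assert back.n_ex == ens.n_ex and back.n_in == ens.n_in
        assert back.correlation == ens.correlation
        for ta, tb in zip(ens.excitatory_trains, back.excitatory_trains):
            np.testing.assert_allclose(ta.times, tb.times, atol=1e-5)

    def test_spiketrain_invariants_enforced(self):
        with pytest.raises(ValueError):
            SpikeTrain(times=np.array([3.0, 2.0]), duration=10.0)
        with pytest.raises(ValueError):
            SpikeTrain(times=np.array([1.0, 11.0]), duration=10.0)
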