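"""Population plasticity runs, distribution and competition classification."""

import numpy as np
import pytest

from stdpop import (
    BoundsPolicy,
    InputEnsemble,
    PopulationExperiment,
    WeightEnsemble,
    classify_distribution,
    run_weight_evolution,
)
from stdpop.config import get_rule_preset
from stdpop.population import classify_competition
from stdpop.rules import PairParams


class TestClassifyDistribution:
    def test_tight_cluster_at_bound_is_unstable(self, rng):
        w = np.clip(rng.normal(0.99, 0.005, 1000), 0, 1)
        assert classify_distribution(w, 1.0) == "unstable_at_bound"

    def test_two_piles_are_bimodal(self, rng):
        w = np.clip(np.concatenate([
            rng.normal(0.03, 0.02, 400), rng.normal(0.97, 0.02, 600)
        ]), 0, 1)
        assert classify_distribution(w, 1.0) == "partially_stable_bimodal"

    def test_interior_hump_is_unimodal(self, rng):
        w = np.clip(rng.normal(0.5, 0.08, 1000), 0, 1)
        assert classify_distribution(w, 1.0) == "stable_unimodal"

    def test_invariant_to_relabeling(self, rng):
        w = np.clip(np.concatenate([
            rng.normal(0.05, 0.03, 500), rng.normal(0.9, 0.05, 500)
        ]), 0, 1)
        assert classify_distribution(w, 1.0) == classify_distribution(
            rng.permutation(w), 1.0
        )


class TestClassifyCompetition:
    def _ensemble(self, wc, wu, w_max=1.0):
        w = np.concatenate([wc, wu])
        mask = np.zeros(w.size, bool)
        mask[: wc.size] = True
        return WeightEnsemble(w, mask, BoundsPolicy("hard", w_max))

    def test_separated_groups_are_hebbian(self, rng):
        ens = self._ensemble(rng.uniform(0.7, 0.9, 500), rng.uniform(0.2, 0.4, 500))
        assert classify_competition(ens, "partially_stable_bimodal") == "hebbian"

    def test_reversed_groups_are_anti_hebbian(self, rng):
        ens = self._ensemble(rng.uniform(0.1, 0.3, 500), rng.uniform(0.6, 0.8, 500))
        assert classify_competition(ens, "stable_unimodal") == "anti_hebbian"

    def test_saturated_population_does_not_compete(self, rng):
        ens = self._ensemble(
            np.full(500, 1.0), np.clip(rng.normal(0.995, 0.004, 500), 0, 1)
        )
        assert classify_competition(ens, "unstable_at_bound") == "none"

    def test_overlapping_groups_are_none(self, rng):
        ens = self._ensemble(rng.uniform(0.4, 0.6, 500), rng.uniform(0.4, 0.6, 500))
        assert classify_competition(ens, "stable_unimodal") == "none"


class TestRunWeightEvolution:
    def test_zero_amplitude_rule_leaves_weights_unchanged(self, neuron):
        rule = PairParams(0.0, 0.0, 20.0, 20.0)
        ens = InputEnsemble.generate(10_000.0, seed=5)
        init = WeightEnsemble.uniform_init(1000, BoundsPolicy("hard", 2.0), seed=5)
        out = run_weight_evolution(rule, ens, init, neuron=neuron,
                                   extend_if_unconverged=False)
        np.testing.assert_array_equal(out.final_weights.weights, init.weights)

    @pytest.mark.parametrize("kind", ["hard", "soft"])
    def test_weights_never_leave_bounds(self, neuron, kind):
        rule = get_rule_preset("fig1_pair_pot_dominant")
        from stdpop.rules import scale_amplitudes

        rule = scale_amplitudes(rule, 20.0)  # violent updates stress the bounds
        ens = InputEnsemble.generate(30_000.0, seed=6)
        init = WeightEnsemble.uniform_init(
            1000, BoundsPolicy(kind, 1.0), 0.6, 0.9, seed=6
        )
        out = run_weight_evolution(rule, ens, init, neuron=neuron,
                                   extend_if_unconverged=False)
        w = out.final_weights.weights
        assert w.min() >= 0.0 and w.max() <= 1.0

    def test_trajectory_is_recorded_on_schedule(self, neuron):
        rule = get_rule_preset("fig1_pair_dep_dominant")
        ens = InputEnsemble.generate(5_000.0, seed=7)
        init = WeightEnsemble.uniform_init(1000, BoundsPolicy("hard", 1.0), seed=7)
        out = run_weight_evolution(rule, ens, init, neuron=neuron,
                                   record_every=500.0, extend_if_unconverged=False)
        assert len(out.trajectory) == 10
        assert out.trajectory["time_s"].iloc[-1] == pytest.approx(5.0)


class TestCompetitionExperiments:
    def test_classification_is_seed_stable(self):
        classes = set()
        for seed in (11, 12):
            res = PopulationExperiment(
                get_rule_preset("fig1_pair_dep_dominant"),
                bounds=BoundsPolicy("hard", 1.0), duration_s=1200.0, c=0.2,
                amplitude_scale=10.0, extend_if_unconverged=False,
            ).run(seed=seed)
            classes.add(res.competition_class)
        assert classes == {"hebbian"}

    def test_uncorrelated_probe_reports_no_competition(self):
        res = PopulationExperiment(
            get_rule_preset("fig1_pair_dep_dominant"),
            bounds=BoundsPolicy("hard", 1.0), duration_s=300.0, c=0.0,
            amplitude_scale=10.0, extend_if_unconverged=False,
        ).run(seed=13)
        assert res.competition_class == "none"

    def test_sweep_over_correlation_reports_no_signal_at_zero_c(self):
        from stdpop import sweep_competition_over_c

        table = sweep_competition_over_c(
            get_rule_preset("fig1_pair_dep_dominant"), c_grid=[0.0, 0.2],
            duration_s=800.0, seed=21,
            bounds=BoundsPolicy("hard", 1.0), extend_if_unconverged=False,
        )
        by_c = table.set_index("c")
        assert by_c.loc[0.0, "competition_class"] == "none"
        assert by_c.loc[0.2, "competition_class"] == "hebbian"
        assert by_c.loc[0.2, "gap"] > 0.05

    def test_invalid_parameters_raise(self):
        from stdpop import run_competition_experiment

        rule = get_rule_preset("fig1_pair_dep_dominant")
        with pytest.raises(ValueError):
            run_competition_experiment(rule, c=1.5, duration_s=1.0)
        with pytest.raises(ValueError):
            run_competition_experiment(rule, c=0.2, frac_correlated=0.0, duration_s=1.0)
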