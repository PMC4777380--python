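"""Analytic and simulated drift, fixed points, and parameter sweeps."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from stdpop import (
    DriftCurve,
    NeuronParams,
    RateTheoryInputs,
    estimate_drift_sim,
    find_fixed_points,
    pair_deviation_rate,
    pair_drift,
    pair_mean_drift,
    triplet_deviation_rate,
    triplet_mean_drift,
)
from stdpop.config import get_rule_preset
from stdpop.drift import analytic_drift_curve, analytic_mean_drift, sweep_phase_diagram
from stdpop.rules import PairParams, TripletParams

PAIR_DEP = get_rule_preset("fig1_pair_dep_dominant")


class TestPairDrift:
    def test_silent_neuron_has_zero_drift(self, neuron, table1_inputs):
        assert pair_drift(0.0, 0.0, PAIR_DEP, neuron, table1_inputs) == pytest.approx(0.0)

    def test_balanced_windows_leave_positive_w_term(self, neuron, table1_inputs):
        balanced = PairParams(0.005, 0.005, 20.0, 20.0)
        assert pair_drift(0.5, 1.0, balanced, neuron, table1_inputs) > 0

    def test_depression_dominant_curve_crosses_down_once(self, neuron, table1_inputs):
        curve = analytic_drift_curve(PAIR_DEP, np.linspace(0.05, 2.0, 60),
                                     neuron, table1_inputs)
        rep = find_fixed_points(
            curve, f=lambda w: pair_mean_drift(w, PAIR_DEP, neuron, table1_inputs)
        )
        assert len(rep.stable) == 1 and not rep.unstable
        ws = rep.stable[0]
        assert pair_mean_drift(0.5 * ws, PAIR_DEP, neuron, table1_inputs) > 0
        assert pair_mean_drift(1.5 * ws, PAIR_DEP, neuron, table1_inputs) < 0

    def test_nontrivial_root_requires_depression_dominance(self, neuron, table1_inputs):
        grid = np.linspace(0.05, 2.5, 60)
        pot = get_rule_preset("fig1_pair_pot_dominant")
        rep_pot = find_fixed_points(analytic_drift_curve(pot, grid, neuron, table1_inputs))
        rep_dep = find_fixed_points(analytic_drift_curve(PAIR_DEP, grid, neuron, table1_inputs))
        assert rep_pot.n_nontrivial == 0
        assert rep_dep.n_nontrivial == 1

    def test_deviation_rate_positive(self, neuron, table1_inputs):
        assert pair_deviation_rate(0.8, PAIR_DEP, neuron, table1_inputs) > 0

    def test_root_finding_agrees_with_sampled_curve(self, neuron, table1_inputs):
        grid = np.linspace(0.05, 2.0, 200)
        curve = analytic_drift_curve(PAIR_DEP, grid, neuron, table1_inputs)
        rep_interp = find_fixed_points(curve)
        rep_refined = find_fixed_points(
            curve, f=lambda w: pair_mean_drift(w, PAIR_DEP, neuron, table1_inputs)
        )
        assert rep_interp.stable[0] == pytest.approx(rep_refined.stable[0], abs=0.01)


class TestTripletDrift:
    def test_reduces_to_pair_without_trace_increments(self, neuron, table1_inputs):
        tri = TripletParams(pair=PAIR_DEP, a_pre=0.0, a_post=0.0,
                            tau_pre=40.0, tau_post=40.0)
        for w in (0.3, 0.7, 1.2):
            assert triplet_mean_drift(w, tri, neuron, table1_inputs) == pytest.approx(
                pair_mean_drift(w, PAIR_DEP, neuron, table1_inputs), rel=1e-12
            )

    def test_deviation_rate_always_positive(self, neuron, table1_inputs):
        tri = get_rule_preset("fig3_triplet_sweep", a_post_over_a_pre=0.2)
        for w in (0.3, 0.8, 1.5):
            assert triplet_deviation_rate(w, tri, neuron, table1_inputs) > 0

    def test_low_ratio_has_stable_then_unstable_fixed_point(self, neuron, table1_inputs):
        tri = get_rule_preset("fig3_triplet_sweep", a_post_over_a_pre=0.2)
        curve = analytic_drift_curve(tri, np.linspace(0.05, 2.0, 80), neuron, table1_inputs)
        rep = find_fixed_points(
            curve, f=lambda w: triplet_mean_drift(w, tri, neuron, table1_inputs)
        )
        assert len(rep.stable) == 1 and len(rep.unstable) == 1
        assert rep.stable[0] < rep.unstable[0]

    def test_high_ratio_has_no_nontrivial_fixed_points(self, neuron, table1_inputs):
        tri = get_rule_preset("fig3_triplet_sweep", a_post_over_a_pre=1.2)
        curve = analytic_drift_curve(tri, np.linspace(0.05, 2.0, 80), neuron, table1_inputs)
        assert find_fixed_points(curve).n_nontrivial == 0


class TestFindFixedPoints:
    def test_linear_drift_yields_single_stable_root(self):
        grid = np.linspace(0.0, 2.0, 21)
        curve = DriftCurve(grid, -0.3 * (grid - 0.8), np.zeros(21), "analytic")
        rep = find_fixed_points(curve)
        assert rep.stable == [pytest.approx(0.8)]

    def test_insignificant_sign_change_is_flagged_not_counted(self):
        grid = np.linspace(0.0, 1.0, 11)
        vals = 1e-6 * np.sin(2 * np.pi * grid)
        curve = DriftCurve(grid, vals, np.full(11, 1e-5), "simulated")
        rep = find_fixed_points(curve)
        assert rep.n_nontrivial == 0
        assert rep.under_resolved

    def test_stability_labels_match_forward_integration(self, neuron, table1_inputs):
        tri = get_rule_preset("fig3_triplet_sweep", a_post_over_a_pre=0.2)
        curve = analytic_drift_curve(tri, np.linspace(0.05, 2.0, 80), neuron, table1_inputs)
        rep = find_fixed_points(
            curve, f=lambda w: triplet_mean_drift(w, tri, neuron, table1_inputs)
        )
        ws, wu = rep.stable[0], rep.unstable[0]

        def rhs(_, y):
            return [analytic_mean_drift(tri, max(y[0], 0.0), neuron, table1_inputs)]

        horizon = 40_000.0  # s; long enough to contract onto the fixed point
        for start in (0.9 * ws, 0.5 * (ws + wu)):
            end = solve_ivp(rhs, (0, horizon), [start], rtol=1e-6).y[0, -1]
            assert end == pytest.approx(ws, abs=0.02)
        end = solve_ivp(rhs, (0, horizon), [1.02 * wu], rtol=1e-6).y[0, -1]
        assert end > wu + 0.3


class TestSimulatedDrift:
    def test_silent_population_has_exactly_zero_drift(self):
        est = estimate_drift_sim(PAIR_DEP, 0.0, sim_seconds=5.0, seed=0)
        assert est.drift == 0.0 and est.post_rate == 0.0

    @pytest.mark.parametrize("w", [1.1, 1.4])
    def test_matches_closed_form_where_excitation_dominates(self, neuron,
                                                            table1_inputs, w):
        """In the suprathreshold regime the frozen-weight estimate and the
        closed-form drift agree; nearer threshold the linear-response
        approximation for the causal term is known to under-predict."""
        est = estimate_drift_sim(PAIR_DEP, w, sim_seconds=150.0, seed=int(10 * w))
        th = pair_mean_drift(w, PAIR_DEP, neuron, table1_inputs)
        assert est.drift == pytest.approx(th, abs=max(3 * est.se, 0.12 * abs(th)))

    def test_probe_slope_recovers_deviation_rate(self, neuron, table1_inputs):
        w = 1.2
        est = estimate_drift_sim(
            PAIR_DEP, w, probe_offsets=(-0.3 * w, 0.3 * w), sim_seconds=200.0,
            seed=77, n_probe_per_offset=150,
        )
        slope, se = est.w_dependent_slope()
        th = pair_deviation_rate(w, PAIR_DEP, neuron, table1_inputs)
        assert slope == pytest.approx(th, abs=max(3 * se, 0.5 * th))

    def test_probe_weights_must_stay_nonnegative(self):
        with pytest.raises(ValueError):
            estimate_drift_sim(PAIR_DEP, 0.2, probe_offsets=(-0.5,), sim_seconds=1.0)


class TestPhaseDiagram:
    def test_pair_family_transition_at_window_balance(self, neuron):
        # A_- tau_- > A_+ tau_+ is exactly the existence condition for the
        # nontrivial fixed point, so the transition sits at ratio 1
        base = PAIR_DEP

        def make(ratio):
            return PairParams(base.a_plus, ratio * base.a_plus,
                              base.tau_plus, base.tau_minus)

        diagram = sweep_phase_diagram(
            make, [0.9, 0.97, 1.03, 1.2], param_name="a_ratio",
            method="analytic", w_grid=np.linspace(0.05, 2.5, 50), neuron=neuron,
        )
        assert diagram.table["has_stable"].tolist() == [False, False, True, True]

    def test_triplet_fixed_points_vanish_earlier_when_potentiation_dominates(
        self, neuron
    ):
        grid = np.arange(0.1, 2.01, 0.1)
        w_grid = np.linspace(0.05, 2.0, 50)

        def largest_stable(pot_dominant):
            diag = sweep_phase_diagram(
                lambda r: get_rule_preset(
                    "fig3_triplet_sweep", a_post_over_a_pre=r,
                    pot_dominant=pot_dominant,
                ),
                grid, param_name="r", method="analytic", w_grid=w_grid, neuron=neuron,
            )
            tab = diag.table
            return tab[tab.has_stable]["r"].max() if tab.has_stable.any() else 0.0

        assert largest_stable(True) < largest_stable(False)
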