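"""Event-driven plasticity rules: windows, traces, bounds, reductions."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stdpop import (
    BoundsPolicy,
    PairParams,
    SuppressionParams,
    TripletParams,
    apply_bounds,
    pair_window,
    triplet_protocol_response,
)
from stdpop.config import get_rule_preset
from stdpop.rules import NmdarParams, SynapseState, on_post_spike, on_pre_spike

from conftest import random_event_sequence


def run_sequence(rule, events):
    """Total candidate weight change of one synapse over an event list."""
    state = SynapseState()
    total = 0.0
    for t, kind in events:
        pot, dep = (on_pre_spike if kind == "pre" else on_post_spike)(rule, state, t)
        total += pot + dep
    return total


class TestPairWindow:
    def test_zero_interval_is_potentiation(self):
        p = PairParams(0.005, 0.004, 20.0, 20.0)
        assert pair_window(0.0, p) == pytest.approx(0.005)

    def test_one_depression_time_constant(self):
        p = PairParams(0.005, 0.004, 20.0, 30.0)
        assert pair_window(-30.0, p) == pytest.approx(-0.004 * math.e**-1)

    @pytest.mark.parametrize("dt", [1e4, -1e4])
    def test_decays_to_zero(self, dt):
        p = PairParams(0.005, 0.004, 20.0, 20.0)
        assert pair_window(dt, p) == pytest.approx(0.0, abs=1e-12)


class TestReductions:
    def test_triplet_with_zero_trace_increments_is_pair(self, rng):
        pair = PairParams(0.005, 0.0051, 16.8, 33.7)
        triplet = TripletParams(pair=pair, a_pre=0.0, a_post=0.0,
                                tau_pre=40.0, tau_post=40.0)
        events = random_event_sequence(rng)
        assert run_sequence(triplet, events) == pytest.approx(
            run_sequence(pair, events), rel=1e-12
        )

    def test_suppression_with_vanishing_memory_is_pair(self, rng):
        # tau_pre, tau_post -> 0: every efficacy is 1 and the rule becomes
        # plain all-to-all pair STDP
        pair = PairParams(0.013, 0.0051, 13.3, 34.5)
        supp = SuppressionParams(pair=pair, tau_pre=1e-6, tau_post=1e-6)
        events = random_event_sequence(rng)
        assert run_sequence(supp, events) == pytest.approx(
            run_sequence(pair, events), rel=1e-9
        )

    def test_isolated_pair_equals_pair_window_under_suppression(self):
        supp = get_rule_preset("table2_suppression")
        state = SynapseState()
        on_pre_spike(supp, state, 100.0)
        pot, dep = on_post_spike(supp, state, 112.0)
        assert pot + dep == pytest.approx(pair_window(12.0, supp.pair))

    def test_nmdar_with_unlimited_pools_tracks_triplet(self, rng):
        """With the receptor pool pinned at rest and messenger saturation
        removed, the NMDAR cascade reduces to trace dynamics of the triplet
        type; the per-event weight changes of the two rules should then be
        strongly proportional on a random spike sequence."""
        nm = NmdarParams(
            a_plus=1.0, a_minus=1.0, a_f_up=0.1, a_f_dn=0.1,
            a_m_up=0.1, a_m_dn=0.1, tau_f_up=20.0, tau_f_dn=30.0,
            tau_m_up=60.0, tau_m_dn=60.0, theta_up=0.0, theta_dn=0.0,
        )
        events = random_event_sequence(rng, n_pre=120, n_post=120, t_max=10_000.0)

        # linearized NMDAR: f_rest == 1, no (1 - M) factors
        fup = fdn = mup = mdn = 0.0
        t_last = 0.0
        lin = []
        for t, kind in events:
            el = t - t_last
            fup *= math.exp(-el / nm.tau_f_up)
            fdn *= math.exp(-el / nm.tau_f_dn)
            mup *= math.exp(-el / nm.tau_m_up)
            mdn *= math.exp(-el / nm.tau_m_dn)
            t_last = t
            if kind == "pre":
                fup += nm.a_f_up
                mdn += nm.a_m_dn * fdn
                lin.append(-nm.a_minus * mdn)
            else:
                mup += nm.a_m_up * fup
                fdn += nm.a_f_dn
                lin.append(nm.a_plus * mup)

        # matched triplet rule: the pair windows play the role of the
        # receptor traces, the triplet traces that of the messengers
        tri = TripletParams(
            pair=PairParams(nm.a_m_up * nm.a_f_up, nm.a_m_dn * nm.a_f_dn,
                            nm.tau_f_up, nm.tau_f_dn),
            a_pre=0.0, a_post=0.0, tau_pre=nm.tau_m_dn, tau_post=nm.tau_m_up,
        )
        # accumulate triplet-style responses per event with messenger-like
        # low-pass filtering of the pair contributions
        state = SynapseState()
        trip = []
        m_up_t = m_dn_t = 0.0
        t_prev = 0.0
        for t, kind in events:
            el = t - t_prev
            m_up_t *= math.exp(-el / nm.tau_m_up)
            m_dn_t *= math.exp(-el / nm.tau_m_dn)
            t_prev = t
            pot, dep = (on_pre_spike if kind == "pre" else on_post_spike)(
                tri, state, t
            )
            if kind == "pre":
                m_dn_t += -dep
                trip.append(-m_dn_t)
            else:
                m_up_t += pot
                trip.append(m_up_t)
        lin, trip = np.array(lin), np.array(trip)
        corr = np.corrcoef(lin, trip)[0, 1]
        assert corr > 0.99


class TestNmdarInvariants:
    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.tuples(st.floats(0.1, 5000.0), st.booleans()),
                    min_size=1, max_size=120))
    def test_state_fractions_conserved_and_bounded(self, raw):
        """f_rest + f_up + f_dn == 1 and all fractions stay in [0, 1] on
        arbitrary spike sequences."""
        nm = get_rule_preset("table2_nmdar")
        events = sorted((t, "pre" if is_pre else "post") for t, is_pre in raw)
        state = SynapseState()
        for t, kind in events:
            (on_pre_spike if kind == "pre" else on_post_spike)(nm, state, t)
            assert state.f_up + state.f_dn + state.f_rest == pytest.approx(1.0)
            for frac in (state.f_up, state.f_dn, state.m_up, state.m_dn):
                assert -1e-12 <= frac <= 1.0 + 1e-12

    def test_states_decay_toward_rest_after_single_post(self):
        nm = get_rule_preset("table2_nmdar")
        state = SynapseState()
        on_post_spike(nm, state, 0.0)
        f_dn0, m_up0 = state.f_dn, state.m_up
        assert f_dn0 == pytest.approx(nm.a_f_dn)  # from a full rest pool
        assert m_up0 == pytest.approx(0.0)        # no up-state receptors yet
        on_pre_spike(nm, state, 1000.0)
        assert state.f_dn == pytest.approx(f_dn0 * math.exp(-1000.0 / nm.tau_f_dn))

    @settings(max_examples=20, deadline=None)
    @given(st.lists(st.tuples(st.floats(0.1, 3000.0), st.booleans()),
                    min_size=1, max_size=80))
    def test_pair_traces_stay_nonnegative(self, raw):
        rule = get_rule_preset("fig3_triplet_sweep")
        events = sorted((t, "pre" if is_pre else "post") for t, is_pre in raw)
        state = SynapseState()
        for t, kind in events:
            (on_pre_spike if kind == "pre" else on_post_spike)(rule, state, t)
            assert min(state.r1, state.o1, state.m_pre, state.m_post) >= 0.0


class TestEventOrdering:
    def test_time_regression_raises(self):
        rule = get_rule_preset("fig1_pair_dep_dominant")
        state = SynapseState()
        on_pre_spike(rule, state, 100.0)
        with pytest.raises(ValueError):
            on_post_spike(rule, state, 50.0)


class TestApplyBounds:
    def test_hard_clips_at_wmax(self):
        policy = BoundsPolicy("hard", 1.0)
        assert apply_bounds(1.0, 0.5, policy) == 1.0
        assert apply_bounds(0.0, -0.5, policy) == 0.0

    def test_soft_kills_potentiation_at_wmax(self):
        policy = BoundsPolicy("soft", 1.0)
        assert apply_bounds(1.0, (0.4, 0.0), policy) == 1.0

    def test_soft_kills_depression_at_zero(self):
        policy = BoundsPolicy("soft", 1.0)
        assert apply_bounds(0.0, (0.0, -0.4), policy) == 0.0

    def test_soft_scales_linearly_in_between(self):
        policy = BoundsPolicy("soft", 1.0)
        out = apply_bounds(0.25, (0.1, -0.1), policy)
        assert out == pytest.approx(0.25 + 0.75 * 0.1 - 0.25 * 0.1)

    def test_entry_outside_bounds_raises(self):
        with pytest.raises(ValueError):
            apply_bounds(1.5, 0.0, BoundsPolicy("hard", 1.0))


class TestTripletProtocol:
    def test_pair_rule_response_is_symmetric(self):
        pair = get_rule_preset("fig1_pair_dep_dominant")
        for dt1, dt2 in [(10.0, 10.0), (5.0, 25.0), (40.0, 15.0)]:
            a = triplet_protocol_response(pair, dt1, dt2, "pre_post_pre")
            b = triplet_protocol_response(pair, dt2, dt1, "post_pre_post")
            assert a == pytest.approx(b, rel=1e-9)
        # equal intervals: the two orderings coincide exactly
        a = triplet_protocol_response(pair, 10.0, 10.0, "pre_post_pre")
        b = triplet_protocol_response(pair, 10.0, 10.0, "post_pre_post")
        assert a == pytest.approx(b, rel=1e-9)

    def test_hippocampal_triplet_prefers_post_pre_post(self):
        tri = get_rule_preset("table2_triplet_hippocampal")
        ppp = triplet_protocol_response(tri, 10.0, 10.0, "pre_post_pre")
        ppo = triplet_protocol_response(tri, 10.0, 10.0, "post_pre_post")
        assert ppo > 0 and ppo > ppp

    def test_suppression_sign_pattern(self):
        sup = get_rule_preset("table2_suppression")
        assert triplet_protocol_response(sup, 10.0, 10.0, "pre_post_pre") > 0
        assert triplet_protocol_response(sup, 10.0, 10.0, "post_pre_post") < 0

    def test_nmdar_sign_pattern_matches_suppression(self):
        nm = get_rule_preset("table2_nmdar")
        assert triplet_protocol_response(nm, 10.0, 10.0, "pre_post_pre") > 0
        assert triplet_protocol_response(nm, 10.0, 10.0, "post_pre_post") < 0

    def test_invalid_pattern_raises(self):
        pair = get_rule_preset("fig1_pair_dep_dominant")
        with pytest.raises(ValueError):
            triplet_protocol_response(pair, 10.0, 10.0, "post_post_post")


class TestParameterValidation:
    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            PairParams(-0.001, 0.005, 20.0, 20.0)

    def test_suppression_time_constants_positive(self):
        pair = PairParams(0.005, 0.005, 20.0, 20.0)
        with pytest.raises(ValueError):
            SuppressionParams(pair=pair, tau_pre=0.0, tau_post=88.0)

    def test_nmdar_fractions_bounded(self):
        with pytest.raises(ValueError):
            replace(get_rule_preset("table2_nmdar"), a_f_up=1.5)
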