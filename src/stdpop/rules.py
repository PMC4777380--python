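"""Spike-timing dependent plasticity rules.

Four rules are implemented as event-driven per-synapse state machines:

pair
    The classical exponential STDP window: potentiation ``A_+ e^{-dt/tau_+}``
    for a pre-before-post pairing (``dt = t_post - t_pre >= 0``), depression
    ``-A_- e^{dt/tau_-}`` otherwise.  All-to-all pairing is handled with
    exponential trace variables (exactly equivalent to enumerating pairs);
    a nearest-neighbor variant pairs each spike with the most recent spike
    of the other type only.

triplet
    Pair-based, plus a presynaptic depression trace ``M_pre`` (incremented
    by ``A_pre`` on each presynaptic spike, decaying with ``tau_pre``) that
    adds to ``A_-``, and a postsynaptic potentiation trace ``M_post``
    (incremented by ``A_post`` on postsynaptic spikes, decaying with
    ``tau_post``) that adds to ``A_+``.  Traces are read just before their
    own-spike increment.

suppression
    Pair-based plasticity in which each spike's efficacy is suppressed by
    its predecessor of the same type: a pre/post pairing contributes
    ``(1 - e^{-dt_pre/tau_pre})(1 - e^{-dt_post/tau_post})`` times the pair
    window, where ``dt_pre`` (``dt_post``) is the interval between the pre
    (post) spike of the pair and the preceding spike on the same side; a
    spike with no predecessor has efficacy 1.  By default every pre/post
    pair contributes with its efficacy product (``all_to_all``, implemented
    with efficacy-weighted traces; this is the reading that reproduces the
    published population behavior of the model); a strict
    ``nearest_neighbor`` variant restricting plasticity to adjacent
    opposite-type spike pairs is also available.

nmdar
    A three-state receptor pool (rest/up/down fractions summing to one) and
    two saturating second messengers.  Presynaptic spikes move rest-state
    receptors up, activate the down messenger in proportion to the
    down-state fraction, and depress the synapse by
    ``A_- [M_dn - theta_dn]_+``; postsynaptic spikes move rest-state
    receptors down, activate the up messenger in proportion to the up-state
    fraction, and potentiate by ``A_+ [M_up - theta_up]_+``.  Receptor and
    messenger increments use pre-spike values; the plasticity step uses the
    just-updated messenger.

Amplitudes are in mV, time constants in ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PairParams",
    "TripletParams",
    "SuppressionParams",
    "NmdarParams",
    "BoundsPolicy",
    "SynapseState",
    "pair_window",
    "on_pre_spike",
    "on_post_spike",
    "apply_bounds",
    "triplet_protocol_response",
    "scale_amplitudes",
]


# --------------------------------------------------------------------------
# parameter bundles


@dataclass(frozen=True)
class PairParams:
    a_plus: float
    a_minus: float
    tau_plus: float
    tau_minus: float
    pairing: str = "all_to_all"

    kind = "pair"

    def __post_init__(self):
        if self.a_plus < 0 or self.a_minus < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("time constants must be positive")
        if self.pairing not in ("all_to_all", "nearest_neighbor"):
            raise ValueError("pairing must be 'all_to_all' or 'nearest_neighbor'")


@dataclass(frozen=True)
class TripletParams:
    pair: PairParams
    a_pre: float
    a_post: float
    tau_pre: float
    tau_post: float

    kind = "triplet"

    def __post_init__(self):
        if self.pair.pairing != "all_to_all":
            raise ValueError("the triplet rule uses all-to-all pairing")
        if self.a_pre < 0 or self.a_post < 0:
            raise ValueError("trace increments must be non-negative")
        if self.tau_pre <= 0 or self.tau_post <= 0:
            raise ValueError("trace time constants must be positive")


@dataclass(frozen=True)
class SuppressionParams:
    pair: PairParams
    tau_pre: float
    tau_post: float

    kind = "suppression"

    def __post_init__(self):
        if self.tau_pre <= 0 or self.tau_post <= 0:
            raise ValueError("suppression time constants must be positive")


@dataclass(frozen=True)
class NmdarParams:
    a_plus: float
    a_minus: float
    a_f_up: float
    a_f_dn: float
    a_m_up: float
    a_m_dn: float
    tau_f_up: float
    tau_f_dn: float
    tau_m_up: float
    tau_m_dn: float
    theta_up: float
    theta_dn: float

    kind = "nmdar"

    def __post_init__(self):
        for name in ("a_f_up", "a_f_dn", "a_m_up", "a_m_dn"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1] (scales a state fraction)")
        for name in ("tau_f_up", "tau_f_dn", "tau_m_up", "tau_m_dn"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.a_plus < 0 or self.a_minus < 0:
            raise ValueError("amplitudes must be non-negative")


PlasticityRule = PairParams | TripletParams | SuppressionParams | NmdarParams


def scale_amplitudes(rule: PlasticityRule, factor: float) -> PlasticityRule:
    """Return a copy of ``rule`` with all mV plasticity amplitudes scaled.

    Scaling ``A_+, A_-`` (and, for the triplet rule, ``A_pre, A_post``)
    by a common factor leaves fixed points of the mean weight unchanged
    while speeding up weight evolution by the same factor; it is the
    reduced-scale protocol used for long population runs.
    """
    if isinstance(rule, PairParams):
        return replace(rule, a_plus=rule.a_plus * factor, a_minus=rule.a_minus * factor)
    if isinstance(rule, TripletParams):
        return replace(
            rule,
            pair=scale_amplitudes(rule.pair, factor),
            a_pre=rule.a_pre * factor,
            a_post=rule.a_post * factor,
        )
    if isinstance(rule, SuppressionParams):
        return replace(rule, pair=scale_amplitudes(rule.pair, factor))
    if isinstance(rule, NmdarParams):
        return replace(rule, a_plus=rule.a_plus * factor, a_minus=rule.a_minus * factor)
    raise TypeError(f"unknown rule {rule!r}")


@dataclass(frozen=True)
class BoundsPolicy:
    """Weight bounds: 'hard' clips to [0, w_max]; 'soft' scales potentiation
    by (1 - w/w_max) and depression by w/w_max before applying."""

    kind: str = "hard"
    w_max: float = 1.0

    def __post_init__(self):
        if self.kind not in ("hard", "soft"):
            raise ValueError("bounds kind must be 'hard' or 'soft'")
        if self.w_max <= 0:
            raise ValueError("w_max must be positive")


# --------------------------------------------------------------------------
# per-synapse state


@dataclass
class SynapseState:
    """Mutable per-synapse plasticity state (reference implementation).

    Only the fields relevant to the owning rule are used.  Traces decay
    lazily: ``t_last`` records the time of the last update.
    """

    w: float = 0.0
    t_last: float = -math.inf
    # pair traces (all-to-all)
    r1: float = 0.0        # presynaptic pairing trace, tau_plus
    o1: float = 0.0        # postsynaptic pairing trace, tau_minus
    # triplet traces
    m_pre: float = 0.0
    m_post: float = 0.0
    # nearest-neighbor bookkeeping
    last_pre_time: float = -math.inf
    last_post_time: float = -math.inf
    eff_pre: float = 1.0
    eff_post: float = 1.0
    # NMDAR receptor and messenger fractions
    f_up: float = 0.0
    f_dn: float = 0.0
    m_up: float = 0.0
    m_dn: float = 0.0

    @property
    def f_rest(self) -> float:
        return 1.0 - self.f_up - self.f_dn

    def _advance(self, t: float, rule: PlasticityRule) -> None:
        if t < self.t_last:
            raise ValueError(
                f"event at t={t} precedes the last processed event at {self.t_last}"
            )
        if not math.isfinite(self.t_last):
            self.t_last = t
            return
        el = t - self.t_last
        if isinstance(rule, (PairParams, TripletParams)):
            pair = rule if isinstance(rule, PairParams) else rule.pair
            self.r1 *= math.exp(-el / pair.tau_plus)
            self.o1 *= math.exp(-el / pair.tau_minus)
            if isinstance(rule, TripletParams):
                self.m_pre *= math.exp(-el / rule.tau_pre)
                self.m_post *= math.exp(-el / rule.tau_post)
        elif isinstance(rule, SuppressionParams):
            self.r1 *= math.exp(-el / rule.pair.tau_plus)
            self.o1 *= math.exp(-el / rule.pair.tau_minus)
        elif isinstance(rule, NmdarParams):
            self.f_up *= math.exp(-el / rule.tau_f_up)
            self.f_dn *= math.exp(-el / rule.tau_f_dn)
            self.m_up *= math.exp(-el / rule.tau_m_up)
            self.m_dn *= math.exp(-el / rule.tau_m_dn)
        self.t_last = t


def pair_window(delta_t: float, params: PairParams) -> float:
    """Weight change for a single pairing with interval ``delta_t = t_post - t_pre``.

    ``delta_t = 0`` is assigned to the potentiation branch.
    """
    if delta_t >= 0:
        return params.a_plus * math.exp(-delta_t / params.tau_plus)
    return -params.a_minus * math.exp(delta_t / params.tau_minus)


def on_pre_spike(rule: PlasticityRule, state: SynapseState, t: float) -> tuple[float, float]:
    """Process a presynaptic spike at time ``t`` (ms).

    Updates ``state`` in place and returns the candidate weight change as a
    ``(potentiation, depression)`` pair (``potentiation >= 0 >=
    depression``), before any bounds policy is applied.
    """
    state._advance(t, rule)
    pot = dep = 0.0
    if isinstance(rule, PairParams):
        if rule.pairing == "all_to_all":
            dep = -rule.a_minus * state.o1
            state.r1 += 1.0
        else:  # nearest neighbor: pair with the most recent postsynaptic spike
            if math.isfinite(state.last_post_time):
                dep = pair_window(state.last_post_time - t, rule)
    elif isinstance(rule, TripletParams):
        dep = -(rule.pair.a_minus + state.m_pre) * state.o1
        state.m_pre += rule.a_pre
        state.r1 += 1.0
    elif isinstance(rule, SuppressionParams):
        gap = t - state.last_pre_time
        eff_new = 1.0 - math.exp(-gap / rule.tau_pre) if math.isfinite(gap) else 1.0
        if rule.pair.pairing == "all_to_all":
            dep = -rule.pair.a_minus * eff_new * state.o1
            state.r1 += eff_new
        elif math.isfinite(state.last_post_time):
            dep = (
                eff_new
                * state.eff_post
                * pair_window(state.last_post_time - t, rule.pair)
            )
        state.eff_pre = eff_new
    elif isinstance(rule, NmdarParams):
        state.f_up += rule.a_f_up * state.f_rest
        state.m_dn += rule.a_m_dn * state.f_dn * (1.0 - state.m_dn)
        dep = -rule.a_minus * max(state.m_dn - rule.theta_dn, 0.0)
    else:
        raise TypeError(f"unknown rule {rule!r}")
    state.last_pre_time = t
    return pot, dep


def on_post_spike(rule: PlasticityRule, state: SynapseState, t: float) -> tuple[float, float]:
    """Process a postsynaptic spike at time ``t`` (ms); see :func:`on_pre_spike`."""
    state._advance(t, rule)
    pot = dep = 0.0
    if isinstance(rule, PairParams):
        if rule.pairing == "all_to_all":
            pot = rule.a_plus * state.r1
            state.o1 += 1.0
        else:
            if math.isfinite(state.last_pre_time):
                pot = pair_window(t - state.last_pre_time, rule)
    elif isinstance(rule, TripletParams):
        pot = (rule.pair.a_plus + state.m_post) * state.r1
        state.m_post += rule.a_post
        state.o1 += 1.0
    elif isinstance(rule, SuppressionParams):
        gap = t - state.last_post_time
        eff_new = 1.0 - math.exp(-gap / rule.tau_post) if math.isfinite(gap) else 1.0
        if rule.pair.pairing == "all_to_all":
            pot = rule.pair.a_plus * eff_new * state.r1
            state.o1 += eff_new
        elif math.isfinite(state.last_pre_time):
            pot = (
                state.eff_pre
                * eff_new
                * pair_window(t - state.last_pre_time, rule.pair)
            )
        state.eff_post = eff_new
    elif isinstance(rule, NmdarParams):
        state.f_dn += rule.a_f_dn * state.f_rest
        state.m_up += rule.a_m_up * state.f_up * (1.0 - state.m_up)
        pot = rule.a_plus * max(state.m_up - rule.theta_up, 0.0)
    else:
        raise TypeError(f"unknown rule {rule!r}")
    state.last_post_time = t
    return pot, dep


def apply_bounds(w: float, delta_w, policy: BoundsPolicy, rule=None) -> float:
    """Apply a candidate weight change under the given bounds policy.

    ``delta_w`` is either a ``(potentiation, depression)`` pair as returned
    by the event handlers, or a signed scalar (its sign then decides which
    soft-bound factor applies).  Soft bounds scale all potentiation
    contributions by ``1 - w/w_max`` and all depression contributions by
    ``w/w_max`` (for the triplet rule this scales the trace contributions
    too, since they enter the same potentiation/depression totals); the
    result is clipped to ``[0, w_max]`` in either policy.
    """
    if not 0.0 <= w <= policy.w_max:
        raise ValueError(f"weight {w} outside [0, {policy.w_max}] on entry")
    if np.isscalar(delta_w):
        pot, dep = (delta_w, 0.0) if delta_w >= 0 else (0.0, delta_w)
    else:
        pot, dep = delta_w
    if policy.kind == "soft":
        pot *= 1.0 - w / policy.w_max
        dep *= w / policy.w_max
    return float(min(max(w + pot + dep, 0.0), policy.w_max))


# --------------------------------------------------------------------------
# the triplet induction-protocol probe


def triplet_protocol_response(
    rule: PlasticityRule,
    delta_t1: float,
    delta_t2: float,
    pattern: str,
    n_repeats: int = 60,
    repeat_interval: float = 1000.0,
) -> float:
    """Net weight change produced by a spike-triplet induction protocol.

    ``pre_post_pre`` places spikes pre(0), post(dt1), pre(dt1+dt2);
    ``post_pre_post`` places post(0), pre(dt1), post(dt1+dt2).  The triplet
    is repeated ``n_repeats`` times every ``repeat_interval`` ms (standard
    induction protocols repeat the pattern; for rules with saturating or
    thresholded state the repetition matters, for the linear rules it simply
    scales the single-triplet response).  The state starts at rest and no
    bounds are applied; returns the accumulated candidate change in mV.
    """
    if pattern not in ("pre_post_pre", "post_pre_post"):
        raise ValueError("pattern must be 'pre_post_pre' or 'post_pre_post'")
    if delta_t1 < 0 or delta_t2 < 0:
        raise ValueError("triplet intervals must be non-negative")
    first = "pre" if pattern == "pre_post_pre" else "post"
    mid = "post" if first == "pre" else "pre"
    events = []
    for rep in range(n_repeats):
        t0 = rep * repeat_interval
        events.append((t0, first, 0))
        events.append((t0 + delta_t1, mid, 1))
        events.append((t0 + delta_t1 + delta_t2, first, 2))
    # stable sort; simultaneous events keep pattern order, pre before post on ties
    events.sort(key=lambda e: (e[0], e[2]))
    state = SynapseState()
    total = 0.0
    for t, kind, _ in events:
        pot, dep = (
            on_pre_spike(rule, state, t) if kind == "pre" else on_post_spike(rule, state, t)
        )
        total += pot + dep
    return total
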