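"""Synaptic drift, fixed points of the mean weight, and parameter sweeps.

The drift is the expected rate of change of a synaptic weight under a
plasticity rule and stationary Poisson input statistics.  It splits into a
baseline part, common to all synapses (through the mean weight's effect on
the postsynaptic rate), and a w-dependent part proportional to the synapse's
own weight (through the transient rate increase each presynaptic spike
causes).  For the pair and triplet rules both parts have closed forms built
on the diffusion-approximation postsynaptic rate; for the suppression and
NMDAR rules the drift is estimated by frozen-weight simulation: the LIF
neuron and the rule are co-simulated with all weights pinned, candidate
modifications are accumulated but never applied, and their time average over
synapses gives the drift with a standard error.

Fixed points of the mean weight are the zeros of the mean drift; a fixed
point is stable when the drift slope there is negative.  The w-dependent
drift at a stable fixed point decides whether individual weights flee the
mean (positive: partially stable, U-shaped distribution) or return to it
(negative: stable unimodal distribution); it is measured by finite
differences on probe-synapse groups offset symmetrically from the mean.

Drift values are reported in mV/s; weights in mV; rates in Hz.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from ._util import as_seedseq
import pandas as pd
from scipy.optimize import brentq

from . import _kernels
from .neuron import NeuronParams, RateTheoryInputs, mean_rate_theory
from .rules import (
    NmdarParams,
    PairParams,
    PlasticityRule,
    SuppressionParams,
    TripletParams,
)
from .spiketrains import InputEnsemble

__all__ = [
    "DriftCurve",
    "FixedPointReport",
    "DriftEstimate",
    "pair_drift",
    "pair_mean_drift",
    "pair_deviation_rate",
    "triplet_mean_drift",
    "triplet_deviation_rate",
    "analytic_mean_drift",
    "analytic_drift_curve",
    "estimate_drift_sim",
    "simulated_drift_curve",
    "find_fixed_points",
    "sweep_phase_diagram",
    "suppression_tau_ratio_sweep",
    "nmdar_amplitude_ratio_sweep",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class DriftCurve:
    """Samples of d<w>/dt (mV/s) against the mean weight <w> (mV)."""

    mean_w_grid: np.ndarray
    drift_values: np.ndarray
    standard_errors: np.ndarray
    source: str  # "analytic" | "simulated"

    def __post_init__(self):
        self.mean_w_grid = np.asarray(self.mean_w_grid, dtype=float)
        self.drift_values = np.asarray(self.drift_values, dtype=float)
        self.standard_errors = np.asarray(self.standard_errors, dtype=float)
        if np.any(np.diff(self.mean_w_grid) <= 0):
            raise ValueError("mean_w grid must be strictly increasing")
        if np.any(self.standard_errors < 0):
            raise ValueError("standard errors must be non-negative")


@dataclass
class FixedPointReport:
    """Nontrivial fixed points of the mean weight, sorted ascending.

    The trivial fixed point at <w> = 0 (silent postsynaptic neuron, no
    plasticity) is reported by flag only and excluded from the list.
    """

    fixed_points: list[tuple[float, str]] = field(default_factory=list)
    includes_trivial_zero: bool = True
    w_dependent_drift_sign_at_stable: str = "undetermined"
    under_resolved: bool = False  # sign changes present but not significant

    @property
    def stable(self) -> list[float]:
        return [w for w, s in self.fixed_points if s == "stable"]

    @property
    def unstable(self) -> list[float]:
        return [w for w, s in self.fixed_points if s == "unstable"]

    @property
    def n_nontrivial(self) -> int:
        return len(self.fixed_points)


@dataclass
class DriftEstimate:
    """Frozen-weight simulation estimate of the drift at one mean weight."""

    mean_w: float
    drift: float            # mV/s, averaged over background synapses
    se: float               # mV/s, across synapses
    probe_drift: dict       # offset (mV) -> (drift, se) on probe synapses
    post_rate: float        # Hz
    sim_seconds: float

    def w_dependent_slope(self) -> tuple[float, float]:
        """Finite-difference slope d(drift)/dw (1/s) from symmetric probes."""
        offs = sorted(self.probe_drift)
        if len(offs) < 2:
            raise ValueError("need at least two probe offsets")
        lo, hi = offs[0], offs[-1]
        (dlo, slo), (dhi, shi) = self.probe_drift[lo], self.probe_drift[hi]
        slope = (dhi - dlo) / (hi - lo)
        se = math.hypot(shi, slo) / (hi - lo)
        return slope, se


# ---------------------------------------------------------------------------
# analytic drift: pair and triplet rules


def _per_ms(rate_hz: float) -> float:
    return rate_hz / 1000.0


def _w_term_coeff(pair: PairParams, neuron: NeuronParams, r_pre_ms: float) -> float:
    """Coefficient of w in the w-dependent drift (per ms per mV)."""
    return (
        pair.a_plus * pair.tau_plus * neuron.tau_s * r_pre_ms
        / ((neuron.tau_s + pair.tau_plus) * (neuron.v_th - neuron.v_r) * neuron.tau_m)
    )


def pair_drift(
    w: float,
    mean_w: float,
    pair: PairParams,
    neuron: NeuronParams,
    inputs: RateTheoryInputs,
) -> float:
    """Average drift (mV/s) of a synapse of weight ``w`` under the pair rule.

    Baseline part ``(A_+ tau_+ - A_- tau_-) r_pre r_post(<w>)`` plus the
    w-dependent part from the transient rate increase the synapse's own
    spikes cause.
    """
    if mean_w < 0:
        raise ValueError("mean_w must be non-negative")
    r = _per_ms(inputs.r_pre)
    rbar = _per_ms(mean_rate_theory(RateTheoryInputs(
        mean_w, inputs.n_ex, inputs.n_in, inputs.r_pre, inputs.r_in), neuron))
    baseline = (pair.a_plus * pair.tau_plus - pair.a_minus * pair.tau_minus) * r * rbar
    return 1000.0 * (baseline + _w_term_coeff(pair, neuron, r) * w)


def pair_mean_drift(
    mean_w: float, pair: PairParams, neuron: NeuronParams, inputs: RateTheoryInputs
) -> float:
    """Drift (mV/s) of the population mean weight: ``pair_drift`` at w = <w>."""
    return pair_drift(mean_w, mean_w, pair, neuron, inputs)


def pair_deviation_rate(
    mean_w: float, pair: PairParams, neuron: NeuronParams, inputs: RateTheoryInputs
) -> float:
    """Growth rate (1/s) of a synapse's deviation from the mean weight.

    This is the coefficient multiplying the deviation in its linearized
    dynamics; it is positive for any positive ``A_+`` and presynaptic rate,
    so pair-rule deviations always grow (partial stability at best).
    """
    return 1000.0 * _w_term_coeff(pair, neuron, _per_ms(inputs.r_pre))


def triplet_mean_drift(
    mean_w: float, triplet: TripletParams, neuron: NeuronParams, inputs: RateTheoryInputs
) -> float:
    """Drift (mV/s) of the mean weight under the triplet rule.

    The average trace values ``A_pre tau_pre r_pre`` and
    ``A_post tau_post r_post`` augment the pair amplitudes, adding a term
    quadratic in the postsynaptic rate (extra potentiation) and one
    proportional to ``r_pre^2`` (extra depression).
    """
    pair = triplet.pair
    r = _per_ms(inputs.r_pre)
    rbar = _per_ms(mean_rate_theory(RateTheoryInputs(
        mean_w, inputs.n_ex, inputs.n_in, inputs.r_pre, inputs.r_in), neuron))
    baseline = (
        pair.a_plus * pair.tau_plus * r * rbar
        + triplet.a_post * triplet.tau_post * pair.tau_plus * r * rbar**2
        - pair.a_minus * pair.tau_minus * r * rbar
        - triplet.a_pre * triplet.tau_pre * pair.tau_minus * r**2 * rbar
    )
    w_coeff = (
        (pair.a_plus + triplet.a_post * triplet.tau_post * rbar)
        * pair.tau_plus * neuron.tau_s * r
        / ((neuron.tau_s + pair.tau_plus) * (neuron.v_th - neuron.v_r) * neuron.tau_m)
    )
    return 1000.0 * (baseline + w_coeff * mean_w)


def triplet_deviation_rate(
    mean_w: float, triplet: TripletParams, neuron: NeuronParams, inputs: RateTheoryInputs
) -> float:
    """Deviation growth rate (1/s) for the triplet rule; always positive."""
    pair = triplet.pair
    r = _per_ms(inputs.r_pre)
    rbar = _per_ms(mean_rate_theory(RateTheoryInputs(
        mean_w, inputs.n_ex, inputs.n_in, inputs.r_pre, inputs.r_in), neuron))
    coeff = (
        (pair.a_plus + triplet.a_post * triplet.tau_post * rbar)
        * pair.tau_plus * neuron.tau_s * r
        / ((neuron.tau_s + pair.tau_plus) * (neuron.v_th - neuron.v_r) * neuron.tau_m)
    )
    return 1000.0 * coeff


def analytic_mean_drift(
    rule: PlasticityRule,
    mean_w: float,
    neuron: NeuronParams,
    inputs: RateTheoryInputs,
) -> float:
    """Closed-form mean drift for the pair and triplet rules (mV/s)."""
    if isinstance(rule, PairParams):
        return pair_mean_drift(mean_w, rule, neuron, inputs)
    if isinstance(rule, TripletParams):
        return triplet_mean_drift(mean_w, rule, neuron, inputs)
    raise TypeError(
        "closed-form drift exists only for the pair and triplet rules; "
        "use estimate_drift_sim for the suppression and NMDAR rules"
    )


def analytic_drift_curve(
    rule: PlasticityRule,
    w_grid: Sequence[float],
    neuron: NeuronParams = NeuronParams(),
    inputs: RateTheoryInputs | None = None,
) -> DriftCurve:
    inputs = inputs or RateTheoryInputs(0.0)
    vals = np.array([analytic_mean_drift(rule, w, neuron, inputs) for w in w_grid])
    return DriftCurve(np.asarray(w_grid, float), vals, np.zeros(len(vals)), "analytic")


# ---------------------------------------------------------------------------
# frozen-weight simulation estimator


def _event_arrays(trains, dt, n_steps):
    steps = np.concatenate([
        (tr.times / dt).astype(np.int64) for tr in trains
    ]) if trains else np.empty(0, dtype=np.int64)
    syn = np.concatenate([
        np.full(tr.n_spikes, i, dtype=np.int64) for i, tr in enumerate(trains)
    ]) if trains else np.empty(0, dtype=np.int64)
    keep = steps < n_steps
    steps, syn = steps[keep], syn[keep]
    order = np.argsort(steps, kind="stable")
    return steps[order], syn[order]


def frozen_post_train(
    weights: np.ndarray,
    ensemble: InputEnsemble,
    neuron: NeuronParams,
    dt: float,
):
    """LIF phase of frozen-weight estimation: the post spike times (ms)."""
    from .neuron import _lif_loop

    n_steps = int(round(ensemble.duration / dt))
    ex_steps, ex_syn = _event_arrays(ensemble.excitatory_trains, dt, n_steps)
    inc_ex = np.zeros(n_steps)
    np.add.at(inc_ex, ex_steps, weights[ex_syn])
    in_steps, _ = _event_arrays(ensemble.inhibitory_trains, dt, n_steps)
    inc_in = np.zeros(n_steps)
    np.add.at(inc_in, in_steps, neuron.w_in)
    post_times = _lif_loop(
        inc_ex, inc_in, dt, neuron.tau_m, neuron.tau_s, neuron.v_th,
        neuron.v_r, neuron.v_r, False, np.empty(0),
    )
    return ex_steps * dt, ex_syn, post_times


def _accumulate(rule, pre_times, pre_syn, post_times, n_ex, tau_plus_batch):
    if isinstance(rule, (PairParams, TripletParams)):
        pair = rule if isinstance(rule, PairParams) else rule.pair
        if isinstance(rule, PairParams) and rule.pairing != "all_to_all":
            raise NotImplementedError(
                "frozen drift estimation implements all-to-all pair STDP"
            )
        a_pre = a_post = 0.0
        tau_pre = tau_post = 1.0
        if isinstance(rule, TripletParams):
            a_pre, a_post = rule.a_pre, rule.a_post
            tau_pre, tau_post = rule.tau_pre, rule.tau_post
        pot, dep = _kernels.accum_pair_triplet(
            pre_times, pre_syn, post_times, n_ex,
            pair.a_plus, pair.a_minus, pair.tau_plus, pair.tau_minus,
            a_pre, a_post, tau_pre, tau_post,
        )
        return {"pot": pot, "dep": dep}
    if isinstance(rule, SuppressionParams):
        if rule.pair.pairing != "all_to_all":
            raise NotImplementedError(
                "frozen drift estimation implements the all-to-all suppression rule"
            )
        batch = (
            np.array([rule.pair.tau_plus]) if tau_plus_batch is None
            else np.asarray(tau_plus_batch, dtype=float)
        )
        pot, dep = _kernels.accum_suppression(
            pre_times, pre_syn, post_times, n_ex,
            rule.pair.a_plus, rule.pair.a_minus, batch, rule.pair.tau_minus,
            rule.tau_pre, rule.tau_post,
        )
        return {"pot_batch": pot, "dep": dep, "tau_plus_batch": batch}
    if isinstance(rule, NmdarParams):
        P, D, mup_raw, mdn_raw = _kernels.accum_nmdar(
            pre_times, pre_syn, post_times, n_ex,
            rule.a_f_up, rule.a_f_dn, rule.a_m_up, rule.a_m_dn,
            rule.tau_f_up, rule.tau_f_dn, rule.tau_m_up, rule.tau_m_dn,
            rule.theta_up, rule.theta_dn,
        )
        return {"P": P, "D": D, "Mup_raw": mup_raw, "Mdn_raw": mdn_raw}
    raise TypeError(f"unknown rule {rule!r}")


def _frozen_run(
    rule: PlasticityRule,
    weights: np.ndarray,
    ensemble: InputEnsemble,
    neuron: NeuronParams,
    dt: float,
    tau_plus_batch: np.ndarray | None = None,
    control_shift_s: float | None = None,
):
    """One frozen-weight estimate: LIF phase, then candidate-plasticity
    replay.  With ``control_shift_s`` set, the replay is repeated against a
    circularly time-shifted copy of the post train; the shifted
    accumulators (suffix ``_ctrl``) share all pre-train randomness with the
    originals but carry no pre-post correlation, so per-synapse differences
    isolate the w-dependent (self-correlation) part of the drift with most
    of the between-synapse variance removed."""
    pre_times, pre_syn, post_times = frozen_post_train(weights, ensemble, neuron, dt)
    acc = _accumulate(rule, pre_times, pre_syn, post_times, ensemble.n_ex, tau_plus_batch)
    n_post = post_times.size
    if control_shift_s is not None:
        shift = round(control_shift_s * 1000.0 / dt) * dt
        shifted = np.sort(np.mod(post_times + shift, ensemble.duration))
        ctrl = _accumulate(rule, pre_times, pre_syn, shifted, ensemble.n_ex, tau_plus_batch)
        for key, val in ctrl.items():
            if key != "tau_plus_batch":
                acc[key + "_ctrl"] = val
    return acc, n_post


def _probe_layout(n_ex: int, mean_w: float, probe_offsets, n_probe_per_offset: int):
    """Weight vector with probe groups at the tail; returns (w, slices)."""
    w = np.full(n_ex, mean_w, dtype=float)
    slices = {}
    pos = n_ex
    for off in probe_offsets:
        sl = slice(pos - n_probe_per_offset, pos)
        if sl.start < 0:
            raise ValueError("too many probe synapses for the population size")
        w[sl] = mean_w + off
        slices[float(off)] = sl
        pos = sl.start
    n_bg = pos
    if n_bg < 2:
        raise ValueError("no background synapses left for the mean-drift estimate")
    return w, slices, n_bg


def _net_per_synapse(acc: dict, rule: PlasticityRule) -> np.ndarray:
    if "pot" in acc:
        return acc["pot"] - acc["dep"]
    if "pot_batch" in acc:
        return acc["pot_batch"][0] - acc["dep"]
    return rule.a_plus * acc["P"] - rule.a_minus * acc["D"]


def estimate_drift_sim(
    rule: PlasticityRule,
    mean_w: float,
    probe_offsets: Sequence[float] = (),
    sim_seconds: float = 200.0,
    seed=None,
    neuron: NeuronParams = NeuronParams(),
    n_ex: int = 1000,
    n_in: int = 250,
    r_pre: float = 10.0,
    r_in: float = 10.0,
    dt: float = 0.1,
    n_probe_per_offset: int = 50,
) -> DriftEstimate:
    """Estimate the drift at one mean weight by frozen-weight simulation.

    All synapses are pinned at ``mean_w`` except the designated probe groups
    (``n_probe_per_offset`` synapses per entry of ``probe_offsets``, placed
    at ``mean_w + offset``); candidate plasticity is accumulated without
    being applied.  Returns the time-averaged drift of the background
    synapses with its standard error across synapses, plus per-offset probe
    drifts for finite-difference estimates of the w-dependent drift.
    """
    if mean_w < 0:
        raise ValueError("mean_w must be non-negative")
    for off in probe_offsets:
        if mean_w + off < 0:
            raise ValueError("probe weights must remain non-negative")
    duration = sim_seconds * 1000.0
    ensemble = InputEnsemble.generate(
        duration, n_ex=n_ex, n_in=n_in, rate_ex=r_pre, rate_in=r_in, seed=seed
    )
    w, probe_slices, n_bg = _probe_layout(n_ex, mean_w, probe_offsets, n_probe_per_offset)
    acc, n_post = _frozen_run(rule, w, ensemble, neuron, dt)
    net = _net_per_synapse(acc, rule) / sim_seconds  # mV/s per synapse
    bg = net[:n_bg]
    drift = float(bg.mean())
    se = float(bg.std(ddof=1) / math.sqrt(n_bg))
    probes = {}
    for off, sl in probe_slices.items():
        vals = net[sl]
        probes[off] = (float(vals.mean()), float(vals.std(ddof=1) / math.sqrt(vals.size)))
    if mean_w > 0 and drift != 0 and se > abs(drift):
        warnings.warn(
            f"drift estimate at <w>={mean_w} has SE {se:.3g} larger than the "
            f"estimate {drift:.3g}; consider a longer simulation",
            stacklevel=2,
        )
    return DriftEstimate(
        mean_w=mean_w,
        drift=drift,
        se=se,
        probe_drift=probes,
        post_rate=1000.0 * n_post / duration,
        sim_seconds=sim_seconds,
    )


def simulated_drift_curve(
    rule: PlasticityRule,
    w_grid: Sequence[float],
    sim_seconds: float = 200.0,
    seed=None,
    **kwargs,
) -> DriftCurve:
    """Frozen-weight drift estimates over a grid of mean weights."""
    ss = as_seedseq(seed)
    children = ss.spawn(len(w_grid))
    drifts, ses = [], []
    for wv, child in zip(w_grid, children):
        est = estimate_drift_sim(rule, wv, sim_seconds=sim_seconds, seed=child, **kwargs)
        drifts.append(est.drift)
        ses.append(est.se)
    return DriftCurve(np.asarray(w_grid, float), np.array(drifts), np.array(ses), "simulated")


# ---------------------------------------------------------------------------
# fixed points


def find_fixed_points(
    curve: DriftCurve,
    f: Callable[[float], float] | None = None,
    se_sigma: float = 2.0,
) -> FixedPointReport:
    """Locate nontrivial fixed points (zeros of the drift) on a sampled curve.

    Sign changes between adjacent grid points are bracketed and refined --
    by root finding on ``f`` when the analytic drift function is supplied,
    otherwise by linear interpolation.  On simulated curves a sign change
    only counts when the drift differs from zero by at least ``se_sigma``
    standard errors on both sides of the bracket; unresolved sign changes
    set ``under_resolved``.  Stability follows the local slope (negative =
    stable).
    """
    x, y, se = curve.mean_w_grid, curve.drift_values, curve.standard_errors
    report = FixedPointReport()
    # grid points landing exactly on a root (rare outside constructed cases)
    for k in np.nonzero(y == 0.0)[0]:
        if 0 < k < len(x) - 1 and y[k - 1] * y[k + 1] < 0.0:
            stability = "stable" if y[k + 1] < y[k - 1] else "unstable"
            report.fixed_points.append((float(x[k]), stability))
    for k in range(len(x) - 1):
        if y[k] == 0.0 or y[k + 1] == 0.0 or y[k] * y[k + 1] > 0.0:
            continue
        if curve.source == "simulated":
            if abs(y[k]) < se_sigma * se[k] or abs(y[k + 1]) < se_sigma * se[k + 1]:
                report.under_resolved = True
                continue
        if f is not None:
            root = brentq(f, x[k], x[k + 1])
        else:
            root = x[k] - y[k] * (x[k + 1] - x[k]) / (y[k + 1] - y[k])
        stability = "stable" if y[k + 1] < y[k] else "unstable"
        report.fixed_points.append((float(root), stability))
    report.fixed_points.sort()
    return report


# ---------------------------------------------------------------------------
# parameter sweeps (phase diagrams)


@dataclass
class PhaseDiagram:
    """Per-grid-value fixed-point reports plus transition brackets."""

    param_name: str
    table: pd.DataFrame
    reports: list[FixedPointReport]

    @property
    def stable_existence_bracket(self) -> tuple[float, float] | None:
        """Grid interval (last value with a stable nontrivial fixed point,
        first following value without)."""
        has = self.table["has_stable"].to_numpy()
        grid = self.table[self.param_name].to_numpy()
        idx = np.nonzero(has)[0]
        if idx.size == 0 or idx[-1] == len(grid) - 1:
            return None
        return float(grid[idx[-1]]), float(grid[idx[-1] + 1])


def sweep_phase_diagram(
    make_rule: Callable[[float], PlasticityRule],
    grid: Sequence[float],
    param_name: str = "param",
    method: str = "analytic",
    w_grid: Sequence[float] | None = None,
    neuron: NeuronParams = NeuronParams(),
    inputs: RateTheoryInputs | None = None,
    sim_seconds: float = 100.0,
    seed=None,
    **sim_kwargs,
) -> PhaseDiagram:
    """Assemble a phase diagram: fixed points of <w> for each parameter value.

    ``make_rule`` maps a grid value to a plasticity rule.  With
    ``method='analytic'`` (pair/triplet) the drift curve is evaluated in
    closed form and roots are refined; with ``method='simulated'`` each grid
    value gets frozen-weight drift estimates over ``w_grid``.
    """
    w_grid = np.asarray(
        np.linspace(0.05, 2.0, 40) if w_grid is None else w_grid, dtype=float
    )
    inputs = inputs or RateTheoryInputs(0.0)
    rows, reports = [], []
    ss = as_seedseq(seed)
    children = ss.spawn(len(grid))
    for gval, child in zip(grid, children):
        rule = make_rule(float(gval))
        if method == "analytic":
            curve = analytic_drift_curve(rule, w_grid, neuron, inputs)
            rep = find_fixed_points(
                curve, f=lambda wv: analytic_mean_drift(rule, wv, neuron, inputs)
            )
        elif method == "simulated":
            curve = simulated_drift_curve(
                rule, w_grid, sim_seconds=sim_seconds, seed=child,
                neuron=neuron, **sim_kwargs,
            )
            rep = find_fixed_points(curve)
        else:
            raise ValueError("method must be 'analytic' or 'simulated'")
        reports.append(rep)
        rows.append({
            param_name: gval,
            "n_nontrivial": rep.n_nontrivial,
            "has_stable": bool(rep.stable),
            "stable_fp": rep.stable[0] if rep.stable else np.nan,
            "unstable_fp": rep.unstable[0] if rep.unstable else np.nan,
        })
    return PhaseDiagram(param_name, pd.DataFrame(rows), reports)


# -- batched sweeps exploiting rule structure -------------------------------


def _batched_frozen_grid(
    rule: PlasticityRule,
    w_grid: np.ndarray,
    probe_rel: float,
    sim_seconds: float,
    seed,
    neuron: NeuronParams,
    n_ex: int,
    n_in: int,
    r_pre: float,
    r_in: float,
    dt: float,
    n_probe: int,
    tau_plus_batch=None,
    control_shift_s=None,
):
    """One frozen run per mean-weight value, with +/-``probe_rel`` probe
    groups; returns the per-synapse accumulators for each grid point."""
    ss = as_seedseq(seed)
    out = []
    secs = np.broadcast_to(np.asarray(sim_seconds, dtype=float), w_grid.shape)
    for wv, T, child in zip(w_grid, secs, ss.spawn(len(w_grid))):
        ensemble = InputEnsemble.generate(
            T * 1000.0, n_ex=n_ex, n_in=n_in, rate_ex=r_pre, rate_in=r_in, seed=child
        )
        offsets = (-probe_rel * wv, probe_rel * wv) if probe_rel else ()
        w, probe_slices, n_bg = _probe_layout(n_ex, wv, offsets, n_probe)
        acc, n_post = _frozen_run(
            rule, w, ensemble, neuron, dt, tau_plus_batch, control_shift_s
        )
        out.append((wv, acc, probe_slices, n_bg, n_post, T))
    return out


def _mean_se(vals: np.ndarray) -> tuple[float, float]:
    return float(vals.mean()), float(vals.std(ddof=1) / math.sqrt(vals.size))


def suppression_tau_ratio_sweep(
    rule_base: SuppressionParams,
    ratio_grid: Sequence[float],
    w_grid: Sequence[float],
    sim_seconds: float = 100.0,
    seed=None,
    neuron: NeuronParams = NeuronParams(),
    n_ex: int = 1000,
    n_in: int = 250,
    r_pre: float = 10.0,
    r_in: float = 10.0,
    dt: float = 0.1,
) -> PhaseDiagram:
    """Phase diagram of the suppression rule over ``tau_+ / tau_-``.

    The pairing structure and the suppression efficacies do not depend on
    ``tau_+``, so a single frozen-weight run per mean-weight value
    accumulates the potentiation for every ratio in the grid
    simultaneously; depression is shared.  Fixed points are then located
    per ratio with the usual significance rule.  ``sim_seconds`` may be an
    array (one duration per mean-weight point): near the critical ratio
    the drift plateau is shallow, so the large-weight points need longer
    runs to reach the 2-SE detection target.
    """
    ratio_grid = np.asarray(ratio_grid, dtype=float)
    w_grid = np.asarray(w_grid, dtype=float)
    tau_batch = ratio_grid * rule_base.pair.tau_minus
    runs = _batched_frozen_grid(
        rule_base, w_grid, 0.0, sim_seconds, seed, neuron,
        n_ex, n_in, r_pre, r_in, dt, 0, tau_plus_batch=tau_batch,
    )
    rows, reports = [], []
    for j, ratio in enumerate(ratio_grid):
        drifts, ses = [], []
        for wv, acc, _, n_bg, _, T in runs:
            net = (acc["pot_batch"][j, :n_bg] - acc["dep"][:n_bg]) / T
            d, s = _mean_se(net)
            drifts.append(d)
            ses.append(s)
        curve = DriftCurve(w_grid, np.array(drifts), np.array(ses), "simulated")
        rep = find_fixed_points(curve)
        reports.append(rep)
        rows.append({
            "tau_ratio": ratio,
            "n_nontrivial": rep.n_nontrivial,
            "has_stable": bool(rep.stable),
            "stable_fp": rep.stable[-1] if rep.stable else np.nan,
            "unstable_fp": rep.unstable[0] if rep.unstable else np.nan,
        })
    return PhaseDiagram("tau_ratio", pd.DataFrame(rows), reports)


@dataclass
class NmdarSweepResult:
    """Amplitude-ratio sweep of the NMDAR rule at fixed kinetics.

    With the plasticity frozen, the drift at mean weight w is
    ``A_- (rho P(w) - D(w))`` where ``rho = A_+/A_-`` and P, D are the
    accumulated thresholded messenger sums per unit time; both the
    fixed-point structure for every ratio and the probe-synapse w-dependent
    drift follow from one set of frozen runs by linearity.
    """

    w_grid: np.ndarray
    P: np.ndarray               # mean potentiation accumulator, 1/s
    D: np.ndarray               # mean depression accumulator, 1/s
    P_se: np.ndarray
    D_se: np.ndarray
    dPdw: np.ndarray            # probe finite differences, 1/(s mV)
    dDdw: np.ndarray
    post_rate: np.ndarray       # Hz
    table: pd.DataFrame
    annihilation_ratio: float | None
    annihilation_bracket: tuple[float, float] | None
    wdrift_sign_change_ratio: float | None

    def drift_curve(self, ratio: float, a_minus: float = 1.0e-3) -> DriftCurve:
        vals = a_minus * (ratio * self.P - self.D)
        ses = a_minus * np.hypot(ratio * self.P_se, self.D_se)
        return DriftCurve(self.w_grid, vals, ses, "simulated")

    def stable_fixed_point(self, ratio: float) -> float | None:
        rep = find_fixed_points(self.drift_curve(ratio))
        return rep.stable[0] if rep.stable else None

    def w_dependent_drift_at(self, ratio: float, w_star: float) -> float:
        """Slope of the drift in the synapse's own weight at w_star (per A_-)."""
        dP = np.interp(w_star, self.w_grid, self.dPdw)
        dD = np.interp(w_star, self.w_grid, self.dDdw)
        return ratio * dP - dD


def nmdar_amplitude_ratio_sweep(
    rule_base: NmdarParams,
    ratio_grid: Sequence[float],
    w_grid: Sequence[float],
    sim_seconds: float = 100.0,
    seed=None,
    neuron: NeuronParams = NeuronParams(),
    n_ex: int = 1000,
    n_in: int = 250,
    r_pre: float = 10.0,
    r_in: float = 10.0,
    dt: float = 0.1,
    probe_rel: float = 0.3,
    n_probe: int = 300,
    refine: int = 40,
    control_shift_s: float = 5.0,
    n_rep: int = 1,
) -> NmdarSweepResult:
    """Sweep ``A_+/A_-`` for the NMDAR rule by frozen-weight simulation.

    One run per mean-weight value accumulates the thresholded messenger sums
    P (potentiation, at postsynaptic spikes) and D (depression, at
    presynaptic spikes) per synapse, including probe groups offset by
    ``+/- probe_rel * w``.  The drift for any amplitude ratio is
    ``rho P - D`` (in units of ``A_-``), so the ratio at which the stable
    and unstable nontrivial fixed points annihilate is the maximum of
    ``D(w)/P(w)`` over the sampled dip, and the ratio at which the
    w-dependent drift at the stable fixed point changes sign is found by
    scanning the stable branch.  Both are reported with their grid brackets.
    """
    ratio_grid = np.asarray(ratio_grid, dtype=float)
    w_grid = np.asarray(w_grid, dtype=float)
    ss = as_seedseq(seed)
    reps = []
    for rep_seed in ss.spawn(n_rep):
        runs = _batched_frozen_grid(
            rule_base, w_grid, probe_rel, sim_seconds, rep_seed, neuron,
            n_ex, n_in, r_pre, r_in, dt, n_probe, control_shift_s=control_shift_s,
        )
        P = np.empty(len(w_grid))
        D = np.empty(len(w_grid))
        P_se = np.empty(len(w_grid))
        D_se = np.empty(len(w_grid))
        dPdw = np.empty(len(w_grid))
        dDdw = np.empty(len(w_grid))
        post_rate = np.empty(len(w_grid))
        for k, (wv, acc, probe_slices, n_bg, n_post, T) in enumerate(runs):
            P[k], P_se[k] = _mean_se(acc["P"][:n_bg] / T)
            D[k], D_se[k] = _mean_se(acc["D"][:n_bg] / T)
            post_rate[k] = 1000.0 * n_post / (T * 1000.0)
            if probe_slices:
                offs = sorted(probe_slices)
                lo_sl, hi_sl = probe_slices[offs[0]], probe_slices[offs[-1]]
                span = offs[-1] - offs[0]
                if span > 0:
                    # control-subtracted probe differences: the shifted-post
                    # replay removes the shared pre-train variance, leaving
                    # the pre-post-correlation (self) part of P and D
                    sP = acc["P"] - acc.get("P_ctrl", 0.0)
                    sD = acc["D"] - acc.get("D_ctrl", 0.0)
                    dPdw[k] = (sP[hi_sl].mean() - sP[lo_sl].mean()) / T / span
                    dDdw[k] = (sD[hi_sl].mean() - sD[lo_sl].mean()) / T / span
                else:
                    dPdw[k] = dDdw[k] = np.nan
            else:
                dPdw[k] = dDdw[k] = np.nan
        reps.append((P, D, P_se, D_se, dPdw, dDdw, post_rate))
    P, D, dPdw, dDdw, post_rate = (
        np.mean([r[i] for r in reps], axis=0) for i in (0, 1, 4, 5, 6)
    )
    P_se, D_se = (
        np.sqrt(np.mean([r[i] ** 2 for r in reps], axis=0)) / math.sqrt(n_rep)
        for i in (2, 3)
    )
    result = NmdarSweepResult(
        w_grid=w_grid, P=P, D=D, P_se=P_se, D_se=D_se,
        dPdw=dPdw, dDdw=dDdw, post_rate=post_rate,
        table=pd.DataFrame(), annihilation_ratio=None,
        annihilation_bracket=None, wdrift_sign_change_ratio=None,
    )
    rows = []
    for ratio in ratio_grid:
        rep = find_fixed_points(result.drift_curve(ratio))
        ws = rep.stable[0] if rep.stable else np.nan
        rows.append({
            "amp_ratio": ratio,
            "n_nontrivial": rep.n_nontrivial,
            "has_stable": bool(rep.stable),
            "stable_fp": ws,
            "unstable_fp": rep.unstable[0] if rep.unstable else np.nan,
            "w_drift_at_stable": (
                result.w_dependent_drift_at(ratio, ws) if rep.stable else np.nan
            ),
        })
    result.table = pd.DataFrame(rows)

    # annihilation: largest ratio with a significant negative dip, i.e. the
    # maximum of D/P over the region where depression can win
    has = result.table["has_stable"].to_numpy()
    idx = np.nonzero(has)[0]
    if idx.size:
        # refine on a dense ratio grid between the last stable grid point and
        # the first unstable one (or the grid end)
        lo = ratio_grid[idx[-1]]
        hi = ratio_grid[idx[-1] + 1] if idx[-1] + 1 < len(ratio_grid) else ratio_grid[-1]
        result.annihilation_bracket = (float(lo), float(hi))
        dense = np.linspace(lo, hi, refine)
        last = lo
        for ratio in dense:
            if find_fixed_points(result.drift_curve(ratio)).stable:
                last = ratio
        result.annihilation_ratio = float(last)
        # w-dependent drift at the stable fixed point along the stable
        # branch; its zero crossing is located by a least-squares line in
        # the ratio (pointwise sign flips are dominated by probe noise as
        # the fixed point migrates across the grid)
        sub = np.linspace(ratio_grid[0], result.annihilation_ratio, max(refine, 40))
        rs, gs = [], []
        for ratio in sub:
            ws = result.stable_fixed_point(ratio)
            if ws is None:
                continue
            rs.append(ratio)
            gs.append(result.w_dependent_drift_at(ratio, ws))
        change = None
        if len(rs) >= 3 and min(gs) < 0.0 < max(gs):
            slope, intercept = np.polyfit(rs, gs, 1)
            if slope > 0:
                root = -intercept / slope
                if rs[0] - 0.5 * (rs[1] - rs[0]) <= root <= rs[-1]:
                    change = root
        result.wdrift_sign_change_ratio = float(change) if change is not None else None
    return result
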