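"""Full plasticity simulations of the synapse population.

The LIF neuron and a plasticity rule are co-simulated with the weights
actually evolving under a bounds policy, until the population reaches a
steady state.  The resulting weight distribution is classified as

``unstable_at_bound``
    at least 90% of the weights lie within 10% of the upper bound (the
    population ran into the bound regardless of structure; the window
    covers the shot-noise boundary layer these rules maintain);

``partially_stable_bimodal``
    the mean is held fixed but individual weights flee to the bounds,
    leaving substantial probability mass clustered at both ends
    (U-shaped distribution);

``stable_unimodal``
    weights gather around an interior mode without piling on the bounds.

The competition probe correlates half of the excitatory inputs (pairwise
coefficient ``c``) and compares the final weights of the correlated and
uncorrelated groups: ``hebbian`` when the correlated group ends
significantly stronger (and the distribution is not simply pinned at the
bound), ``anti_hebbian`` for the opposite sign, ``none`` otherwise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._util import as_seedseq
import pandas as pd
from scipy import stats as sps

from . import _kernels
from ._stats import kde_mode_count
from .drift import _event_arrays
from .neuron import NeuronParams
from .rules import (
    BoundsPolicy,
    NmdarParams,
    PairParams,
    PlasticityRule,
    SuppressionParams,
    TripletParams,
)
from .spiketrains import InputEnsemble

__all__ = [
    "WeightEnsemble",
    "ExperimentOutcome",
    "run_weight_evolution",
    "run_competition_experiment",
    "sweep_competition_over_c",
    "classify_distribution",
    "classify_competition",
]


@dataclass
class WeightEnsemble:
    """The excitatory weight vector with group labels and its bounds policy."""

    weights: np.ndarray
    correlated_mask: np.ndarray
    bounds: BoundsPolicy

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.correlated_mask = np.asarray(self.correlated_mask, dtype=bool)
        if self.weights.shape != self.correlated_mask.shape:
            raise ValueError("weights and correlated_mask must have the same length")
        if np.any(self.weights < 0) or np.any(self.weights > self.bounds.w_max):
            raise ValueError("weights must lie within [0, w_max]")

    @classmethod
    def uniform_init(
        cls,
        n_ex: int,
        bounds: BoundsPolicy,
        low: float = 0.3,
        high: float = 0.7,
        correlated_mask=None,
        seed=None,
    ) -> "WeightEnsemble":
        rng = np.random.default_rng(seed)
        mask = (
            np.zeros(n_ex, dtype=bool) if correlated_mask is None
            else np.asarray(correlated_mask, dtype=bool)
        )
        return cls(rng.uniform(low, high, size=n_ex), mask, bounds)

    @property
    def mean(self) -> float:
        return float(self.weights.mean())

    def group_means(self) -> tuple[float, float]:
        """(correlated mean, uncorrelated mean); NaN for an empty group."""
        c = self.correlated_mask
        mc = float(self.weights[c].mean()) if c.any() else math.nan
        mu = float(self.weights[~c].mean()) if (~c).any() else math.nan
        return mc, mu


@dataclass
class ExperimentOutcome:
    final_weights: WeightEnsemble
    trajectory: pd.DataFrame     # time_s, mean_w, mean_corr, mean_unc
    distribution_class: str
    competition_class: str
    post_rate: float             # Hz over the whole run
    n_modes: int                 # KDE cross-check diagnostic
    converged: bool
    extended: bool
    seed: int | None
    config: dict = field(default_factory=dict)


def classify_distribution(
    weights: WeightEnsemble | np.ndarray,
    w_max: float | None = None,
    bound_frac: float = 0.10,
    bound_mass: float = 0.90,
    prominence_frac: float = 0.05,
) -> str:
    """Classify a steady-state weight distribution.

    ``unstable_at_bound`` when at least ``bound_mass`` of the weights lie
    within ``bound_frac * w_max`` of the upper bound (the depression shot
    noise of these rules maintains an intrinsic boundary layer of a few
    percent of ``w_max`` below the bound, so the window must be wider than
    that layer); otherwise the kernel-density mode structure decides:
    two or more prominent modes give ``partially_stable_bimodal``
    (U-shaped: individual weights flee the stable mean toward both
    bounds), a single mode gives ``stable_unimodal``.
    """
    if isinstance(weights, WeightEnsemble):
        w = weights.weights
        w_max = weights.bounds.w_max
    else:
        w = np.asarray(weights, dtype=float)
        if w_max is None:
            raise ValueError("w_max required when passing a bare array")
    if np.mean(w >= (1.0 - bound_frac) * w_max) >= bound_mass:
        return "unstable_at_bound"
    if kde_mode_count(w, w_max, prominence_frac=prominence_frac) >= 2:
        return "partially_stable_bimodal"
    return "stable_unimodal"


def classify_competition(
    final: WeightEnsemble,
    distribution_class: str,
    alpha: float = 0.01,
    min_gap_frac: float = 0.02,
) -> str:
    """Hebbian / anti-Hebbian / none from the final group weight samples.

    Requires both statistical significance (Welch test at ``alpha``) and a
    practically meaningful group separation (at least ``min_gap_frac`` of
    the weight range) — two saturated piles hugging the same bound differ
    by rounding, not competition.
    """
    c = final.correlated_mask
    if not c.any() or c.all():
        return "none"
    wc, wu = final.weights[c], final.weights[~c]
    gap = float(wc.mean() - wu.mean())
    if abs(gap) < min_gap_frac * final.bounds.w_max:
        return "none"
    tstat, pval = sps.ttest_ind(wc, wu, equal_var=False)
    if not pval < alpha:
        return "none"
    if tstat > 0:
        # a population pinned at the bound has not competed, merely saturated
        return "none" if distribution_class == "unstable_at_bound" else "hebbian"
    return "anti_hebbian"


def _rule_kernel_call(
    rule: PlasticityRule,
    ex_steps, ex_syn, inc_in, w, dt, n_steps,
    neuron: NeuronParams,
    bounds: BoundsPolicy,
    rec_stride: int,
    corr_mask: np.ndarray,
):
    bounds_kind = 0 if bounds.kind == "hard" else 1
    common = (ex_steps, ex_syn, inc_in, w, dt, n_steps,
              neuron.tau_m, neuron.tau_s, neuron.v_th, neuron.v_r)
    tail = (bounds_kind, bounds.w_max, rec_stride, corr_mask)
    if isinstance(rule, (PairParams, TripletParams)):
        pair = rule if isinstance(rule, PairParams) else rule.pair
        if isinstance(rule, PairParams) and rule.pairing != "all_to_all":
            raise NotImplementedError(
                "population simulations implement all-to-all pair STDP"
            )
        a_pre = a_post = 0.0
        tau_pre = tau_post = 1.0
        if isinstance(rule, TripletParams):
            a_pre, a_post = rule.a_pre, rule.a_post
            tau_pre, tau_post = rule.tau_pre, rule.tau_post
        return _kernels.evolve_pair_triplet(
            *common,
            pair.a_plus, pair.a_minus, pair.tau_plus, pair.tau_minus,
            a_pre, a_post, tau_pre, tau_post, *tail,
        )
    if isinstance(rule, SuppressionParams):
        kernel = (
            _kernels.evolve_suppression
            if rule.pair.pairing == "all_to_all"
            else _kernels.evolve_suppression_nn
        )
        return kernel(
            *common,
            rule.pair.a_plus, rule.pair.a_minus,
            rule.pair.tau_plus, rule.pair.tau_minus,
            rule.tau_pre, rule.tau_post, *tail,
        )
    if isinstance(rule, NmdarParams):
        return _kernels.evolve_nmdar(
            *common,
            rule.a_plus, rule.a_minus,
            rule.a_f_up, rule.a_f_dn, rule.a_m_up, rule.a_m_dn,
            rule.tau_f_up, rule.tau_f_dn, rule.tau_m_up, rule.tau_m_dn,
            rule.theta_up, rule.theta_dn, *tail,
        )
    raise TypeError(f"unknown rule {rule!r}")


def _evolve_on_ensemble(
    rule, ensemble: InputEnsemble, weights: np.ndarray, bounds, neuron, dt,
    rec_stride: int, corr_mask,
):
    n_steps = int(round(ensemble.duration / dt))
    ex_steps, ex_syn = _event_arrays(ensemble.excitatory_trains, dt, n_steps)
    in_steps, _ = _event_arrays(ensemble.inhibitory_trains, dt, n_steps)
    inc_in = np.zeros(n_steps)
    np.add.at(inc_in, in_steps, neuron.w_in)
    return _rule_kernel_call(
        rule, ex_steps, ex_syn, inc_in, weights, dt, n_steps,
        neuron, bounds, rec_stride, corr_mask.astype(np.bool_),
    )


def _is_converged(traj: pd.DataFrame, w_max: float, drift_tol: float = 0.01) -> bool:
    """Steady state: |d<w>/dt| over the last 20% below drift_tol * w_max / 100 s."""
    tail = traj.iloc[int(len(traj) * 0.8):]
    if len(tail) < 2:
        return True
    span_s = tail["time_s"].iloc[-1] - tail["time_s"].iloc[0]
    if span_s <= 0:
        return True
    slope = (tail["mean_w"].iloc[-1] - tail["mean_w"].iloc[0]) / span_s
    return abs(slope) < drift_tol * w_max / 100.0


def run_weight_evolution(
    rule: PlasticityRule,
    ensemble: InputEnsemble,
    init: WeightEnsemble,
    duration: float | None = None,
    neuron: NeuronParams = NeuronParams(),
    dt: float = 0.1,
    record_every: float = 1000.0,
    chunk_seconds: float = 100.0,
    extend_if_unconverged: bool = True,
    seed=None,
) -> ExperimentOutcome:
    """Co-simulate the LIF neuron and the plasticity rule to steady state.

    The provided input ensemble is consumed first; if ``duration`` (ms)
    exceeds it, further statistically identical input chunks of
    ``chunk_seconds`` are generated from seeds spawned off ``seed`` (per-
    synapse plasticity traces restart at each chunk boundary, a sub-permille
    effect for chunks much longer than the trace time constants).  If the
    mean weight has not settled by the end, the run is extended once by 50%
    with a warning.
    """
    weights = init.weights.copy()
    corr_mask = init.correlated_mask
    bounds = init.bounds
    duration = ensemble.duration if duration is None else duration
    rec_stride = max(int(round(record_every / dt)), 1)
    ss = as_seedseq(seed)

    trajs = []
    t_offset = 0.0
    n_post_total = 0

    def run_chunk(chunk_ensemble):
        nonlocal t_offset, n_post_total
        traj, n_post = _evolve_on_ensemble(
            rule, chunk_ensemble, weights, bounds, neuron, dt, rec_stride, corr_mask
        )
        n_rec = traj.shape[0]
        times = t_offset + (np.arange(1, n_rec + 1)) * rec_stride * dt / 1000.0
        trajs.append(pd.DataFrame({
            "time_s": times,
            "mean_w": traj[:, 0],
            "mean_corr": traj[:, 1],
            "mean_unc": traj[:, 2],
        }))
        t_offset += chunk_ensemble.duration / 1000.0
        n_post_total += n_post

    run_chunk(ensemble)
    remaining = duration - ensemble.duration
    spec = dict(
        n_ex=ensemble.n_ex, n_in=ensemble.n_in,
        rate_ex=ensemble.rate_ex, rate_in=ensemble.rate_in,
        correlation=ensemble.correlation,
    )
    frac_corr = corr_mask.mean()

    def fresh_chunk(ms):
        return InputEnsemble.generate(
            ms, frac_correlated=frac_corr, seed=ss.spawn(1)[0], **spec
        )

    while remaining > 1e-9:
        ms = min(chunk_seconds * 1000.0, remaining)
        run_chunk(fresh_chunk(ms))
        remaining -= ms

    traj = pd.concat(trajs, ignore_index=True)
    converged = _is_converged(traj, bounds.w_max)
    extended = False
    if not converged and extend_if_unconverged:
        warnings.warn(
            "mean weight had not settled at the end of the run; extending once by 50%",
            stacklevel=2,
        )
        extended = True
        extra = 0.5 * duration
        while extra > 1e-9:
            ms = min(chunk_seconds * 1000.0, extra)
            run_chunk(fresh_chunk(ms))
            extra -= ms
        traj = pd.concat(trajs, ignore_index=True)
        converged = _is_converged(traj, bounds.w_max)

    final = WeightEnsemble(weights, corr_mask, bounds)
    dist_class = classify_distribution(final)
    comp_class = classify_competition(final, dist_class)
    return ExperimentOutcome(
        final_weights=final,
        trajectory=traj,
        distribution_class=dist_class,
        competition_class=comp_class,
        post_rate=1000.0 * n_post_total / (t_offset * 1000.0),
        n_modes=kde_mode_count(weights, bounds.w_max),
        converged=converged,
        extended=extended,
        seed=seed if isinstance(seed, int) else None,
        config={"rule": repr(rule), "bounds": repr(bounds), "duration_ms": t_offset * 1000.0},
    )


def run_competition_experiment(
    rule: PlasticityRule,
    c: float,
    frac_correlated: float = 0.5,
    duration_s: float = 2000.0,
    bounds: BoundsPolicy = BoundsPolicy(),
    neuron: NeuronParams = NeuronParams(),
    n_ex: int = 1000,
    n_in: int = 250,
    r_pre: float = 10.0,
    r_in: float = 10.0,
    init_low: float = 0.3,
    init_high: float = 0.7,
    dt: float = 0.1,
    chunk_seconds: float = 100.0,
    seed=None,
    extend_if_unconverged: bool = True,
) -> ExperimentOutcome:
    """Correlate a fraction of the inputs and test for synaptic competition.

    Runs :func:`run_weight_evolution` with a correlated input subgroup at
    pairwise coefficient ``c``; the outcome's ``competition_class`` reports
    whether the correlated group won (hebbian), lost (anti_hebbian) or
    neither.
    """
    if not 0.0 <= c <= 1.0:
        raise ValueError("c must lie in [0, 1]")
    if not 0.0 < frac_correlated < 1.0:
        raise ValueError("frac_correlated must lie in (0, 1)")
    ss = as_seedseq(seed)
    ss_in, ss_w, ss_run = ss.spawn(3)
    first_ms = min(chunk_seconds * 1000.0, duration_s * 1000.0)
    ensemble = InputEnsemble.generate(
        first_ms, n_ex=n_ex, n_in=n_in, rate_ex=r_pre, rate_in=r_in,
        correlation=c, frac_correlated=frac_correlated, seed=ss_in,
    )
    init = WeightEnsemble.uniform_init(
        n_ex, bounds, init_low, init_high,
        correlated_mask=ensemble.correlated_mask, seed=ss_w,
    )
    out = run_weight_evolution(
        rule, ensemble, init, duration=duration_s * 1000.0, neuron=neuron,
        dt=dt, chunk_seconds=chunk_seconds, seed=ss_run,
        extend_if_unconverged=extend_if_unconverged,
    )
    out.config.update({"c": c, "frac_correlated": frac_correlated})
    return out


def sweep_competition_over_c(
    rule: PlasticityRule,
    c_grid: Sequence[float],
    seed=None,
    **kwargs,
) -> pd.DataFrame:
    """One competition experiment per correlation level.

    Returns a table with the competition class and the correlated-minus-
    uncorrelated group-mean gap for each ``c``.
    """
    rows = []
    ss = as_seedseq(seed)
    for c, child in zip(c_grid, ss.spawn(len(c_grid))):
        out = run_competition_experiment(rule, c=float(c), seed=child, **kwargs)
        mc, mu = out.final_weights.group_means()
        rows.append({
            "c": c,
            "competition_class": out.competition_class,
            "distribution_class": out.distribution_class,
            "mean_corr": mc,
            "mean_unc": mu,
            "gap": mc - mu,
        })
    return pd.DataFrame(rows)
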