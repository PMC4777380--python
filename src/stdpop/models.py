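"""Model/Results front end.

Two model classes tie the pipeline together in the style of statistical
modelling packages: construct the model from a plasticity rule and an input
description, call ``fit``/``run``, and inspect the returned results object
(estimates, uncertainties, diagnostics, ``summary()``).

``DriftModel``
    mean-weight drift as a function of <w>: closed form for the pair and
    triplet rules, frozen-weight simulation for any rule; the results carry
    the drift curve with standard errors, the fixed points with stability
    labels, and the sign of the w-dependent drift at the stable fixed point.

``PopulationExperiment``
    a full plasticity run of the synapse population, returning the final
    weight distribution, its class, and the competition class when part of
    the inputs are correlated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._util import as_seedseq
import pandas as pd

from .drift import (
    DriftCurve,
    DriftEstimate,
    FixedPointReport,
    analytic_drift_curve,
    analytic_mean_drift,
    estimate_drift_sim,
    find_fixed_points,
    pair_deviation_rate,
    triplet_deviation_rate,
)
from .neuron import NeuronParams, RateTheoryInputs
from .population import ExperimentOutcome, run_competition_experiment
from .rules import BoundsPolicy, PairParams, PlasticityRule, TripletParams

__all__ = ["DriftModel", "DriftResults", "PopulationExperiment", "PopulationResults"]


@dataclass
class DriftResults:
    """Fitted drift curve, fixed points and deviation diagnostics."""

    model: "DriftModel"
    curve: DriftCurve
    fixed_points: FixedPointReport
    method: str
    estimates: list[DriftEstimate] = field(default_factory=list)
    deviation_rate_at_stable: float | None = None  # 1/s; analytic rules only
    w_dependent_slope: tuple[float, float] | None = None  # simulated probe slope
    seed: int | None = None

    @property
    def stable_fixed_points(self) -> list[float]:
        return self.fixed_points.stable

    @property
    def unstable_fixed_points(self) -> list[float]:
        return self.fixed_points.unstable

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mean_w_mV": self.curve.mean_w_grid,
            "drift_mV_per_s": self.curve.drift_values,
            "se_mV_per_s": self.curve.standard_errors,
        })

    def summary(self) -> str:
        lines = [
            f"Drift analysis ({self.method}) -- rule: {self.model.rule.kind}",
            f"  mean-weight grid: [{self.curve.mean_w_grid[0]:g}, "
            f"{self.curve.mean_w_grid[-1]:g}] mV, {self.curve.mean_w_grid.size} points",
            f"  trivial fixed point at <w> = 0: "
            f"{'yes' if self.fixed_points.includes_trivial_zero else 'no'}",
        ]
        if self.fixed_points.fixed_points:
            for w, s in self.fixed_points.fixed_points:
                lines.append(f"  nontrivial fixed point: <w>* = {w:.4f} mV ({s})")
        else:
            lines.append("  no nontrivial fixed points")
        if self.fixed_points.under_resolved:
            lines.append("  note: some sign changes were not significant at 2 SE")
        if self.deviation_rate_at_stable is not None:
            lines.append(
                f"  deviation growth rate at stable fp: "
                f"{self.deviation_rate_at_stable:.3e} 1/s"
            )
        if self.w_dependent_slope is not None:
            slope, se = self.w_dependent_slope
            lines.append(
                f"  w-dependent drift slope at stable fp: {slope:.3e} +/- {se:.3e} 1/s"
            )
        lines.append(
            "  w-dependent drift sign at stable fp: "
            f"{self.fixed_points.w_dependent_drift_sign_at_stable}"
        )
        return "\n".join(lines)


class DriftModel:
    """Mean-weight drift of a plasticity rule at a fixed operating point.

    Parameters
    ----------
    rule : plasticity rule parameter bundle
    neuron : LIF constants
    n_ex, n_in, r_pre, r_in : input population sizes and rates (Hz)
    w_grid : mean-weight grid (mV) on which the drift is evaluated
    """

    def __init__(
        self,
        rule: PlasticityRule,
        neuron: NeuronParams = NeuronParams(),
        n_ex: int = 1000,
        n_in: int = 250,
        r_pre: float = 10.0,
        r_in: float = 10.0,
        w_grid: Sequence[float] | None = None,
    ):
        self.rule = rule
        self.neuron = neuron
        self.n_ex = n_ex
        self.n_in = n_in
        self.r_pre = r_pre
        self.r_in = r_in
        self.w_grid = np.asarray(
            np.linspace(0.05, 2.0, 40) if w_grid is None else w_grid, dtype=float
        )

    def _inputs(self) -> RateTheoryInputs:
        return RateTheoryInputs(0.0, self.n_ex, self.n_in, self.r_pre, self.r_in)

    def fit(
        self,
        method: str = "auto",
        sim_seconds: float = 200.0,
        seed=None,
        probe_rel: float = 0.1,
        dt: float = 0.1,
    ) -> DriftResults:
        """Evaluate or estimate the drift curve and locate its fixed points.

        ``method='analytic'`` uses the closed-form drift (pair/triplet only);
        ``method='simulated'`` runs frozen-weight simulations on the grid,
        with probe synapses at ``+/- probe_rel * <w>`` providing the
        w-dependent drift at the stable fixed point; ``'auto'`` picks the
        closed form when one exists.
        """
        if method == "auto":
            method = (
                "analytic" if isinstance(self.rule, (PairParams, TripletParams))
                else "simulated"
            )
        if method == "analytic":
            return self._fit_analytic()
        if method == "simulated":
            return self._fit_simulated(sim_seconds, seed, probe_rel, dt)
        raise ValueError("method must be 'auto', 'analytic' or 'simulated'")

    def _fit_analytic(self) -> DriftResults:
        inputs = self._inputs()
        curve = analytic_drift_curve(self.rule, self.w_grid, self.neuron, inputs)
        report = find_fixed_points(
            curve, f=lambda w: analytic_mean_drift(self.rule, w, self.neuron, inputs)
        )
        dev = None
        if report.stable:
            ws = report.stable[0]
            if isinstance(self.rule, PairParams):
                dev = pair_deviation_rate(ws, self.rule, self.neuron, inputs)
            else:
                dev = triplet_deviation_rate(ws, self.rule, self.neuron, inputs)
            report.w_dependent_drift_sign_at_stable = (
                "positive" if dev > 0 else "negative"
            )
        return DriftResults(
            model=self, curve=curve, fixed_points=report, method="analytic",
            deviation_rate_at_stable=dev,
        )

    def _fit_simulated(self, sim_seconds, seed, probe_rel, dt) -> DriftResults:
        ss = as_seedseq(seed)
        estimates = []
        for wv, child in zip(self.w_grid, ss.spawn(len(self.w_grid))):
            offsets = (-probe_rel * wv, probe_rel * wv) if probe_rel and wv > 0 else ()
            estimates.append(estimate_drift_sim(
                self.rule, wv, probe_offsets=offsets, sim_seconds=sim_seconds,
                seed=child, neuron=self.neuron, n_ex=self.n_ex, n_in=self.n_in,
                r_pre=self.r_pre, r_in=self.r_in, dt=dt,
            ))
        curve = DriftCurve(
            self.w_grid,
            np.array([e.drift for e in estimates]),
            np.array([e.se for e in estimates]),
            "simulated",
        )
        report = find_fixed_points(curve)
        slope = None
        if report.stable:
            ws = report.stable[0]
            k = int(np.argmin(np.abs(self.w_grid - ws)))
            if estimates[k].probe_drift:
                slope = estimates[k].w_dependent_slope()
                sig = abs(slope[0]) > 2.0 * slope[1]
                report.w_dependent_drift_sign_at_stable = (
                    ("positive" if slope[0] > 0 else "negative") if sig else "undetermined"
                )
        return DriftResults(
            model=self, curve=curve, fixed_points=report, method="simulated",
            estimates=estimates, w_dependent_slope=slope,
            seed=seed if isinstance(seed, int) else None,
        )


@dataclass
class PopulationResults:
    """Outcome of a full population plasticity run."""

    model: "PopulationExperiment"
    outcome: ExperimentOutcome

    @property
    def distribution_class(self) -> str:
        return self.outcome.distribution_class

    @property
    def competition_class(self) -> str:
        return self.outcome.competition_class

    @property
    def final_weights(self) -> np.ndarray:
        return self.outcome.final_weights.weights

    @property
    def trajectory(self) -> pd.DataFrame:
        return self.outcome.trajectory

    def group_means(self) -> tuple[float, float]:
        return self.outcome.final_weights.group_means()

    def summary(self) -> str:
        o = self.outcome
        lines = [
            f"Population experiment -- rule: {self.model.rule.kind}, "
            f"bounds: {self.model.bounds.kind} (w_max = {self.model.bounds.w_max:g} mV)",
            f"  simulated {o.trajectory['time_s'].iloc[-1]:.0f} s, "
            f"postsynaptic rate {o.post_rate:.1f} Hz",
            f"  final mean weight: {o.final_weights.mean:.4f} mV",
            f"  distribution class: {o.distribution_class} "
            f"(KDE modes: {o.n_modes}; converged: {o.converged})",
        ]
        mc, mu = o.final_weights.group_means()
        if not math.isnan(mc) and not math.isnan(mu):
            lines.append(
                f"  group means (corr/uncorr): {mc:.4f} / {mu:.4f} mV "
                f"-> competition: {o.competition_class}"
            )
        return "\n".join(lines)


class PopulationExperiment:
    """Full plasticity run of the synapse population, optionally with a
    correlated input subgroup (the competition probe).

    Parameters mirror the standard operating point; ``amplitude_scale``
    multiplies all plasticity amplitudes (a pure time-rescaling of the
    weight dynamics that leaves fixed points in place), allowing reduced-
    duration runs.
    """

    def __init__(
        self,
        rule: PlasticityRule,
        bounds: BoundsPolicy = BoundsPolicy(),
        duration_s: float = 2000.0,
        c: float = 0.0,
        frac_correlated: float = 0.5,
        neuron: NeuronParams = NeuronParams(),
        n_ex: int = 1000,
        n_in: int = 250,
        r_pre: float = 10.0,
        r_in: float = 10.0,
        init_low: float = 0.3,
        init_high: float = 0.7,
        dt: float = 0.1,
        chunk_seconds: float = 100.0,
        amplitude_scale: float = 1.0,
        extend_if_unconverged: bool = True,
    ):
        from .rules import scale_amplitudes

        self.rule = rule if amplitude_scale == 1.0 else scale_amplitudes(rule, amplitude_scale)
        self.bounds = bounds
        self.duration_s = duration_s
        self.c = c
        self.frac_correlated = frac_correlated
        self.neuron = neuron
        self.n_ex = n_ex
        self.n_in = n_in
        self.r_pre = r_pre
        self.r_in = r_in
        self.init_low = init_low
        self.init_high = init_high
        self.dt = dt
        self.chunk_seconds = chunk_seconds
        self.amplitude_scale = amplitude_scale
        self.extend_if_unconverged = extend_if_unconverged

    def run(self, seed=None) -> PopulationResults:
        outcome = run_competition_experiment(
            self.rule,
            c=self.c,
            frac_correlated=self.frac_correlated if self.c > 0 else 0.5,
            duration_s=self.duration_s,
            bounds=self.bounds,
            neuron=self.neuron,
            n_ex=self.n_ex,
            n_in=self.n_in,
            r_pre=self.r_pre,
            r_in=self.r_in,
            init_low=self.init_low,
            init_high=self.init_high,
            dt=self.dt,
            chunk_seconds=self.chunk_seconds,
            seed=seed,
            extend_if_unconverged=self.extend_if_unconverged,
        )
        return PopulationResults(model=self, outcome=outcome)
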