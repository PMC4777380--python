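"""Leaky integrate-and-fire neuron with exponential current-based synapses.

The membrane potential obeys

    tau_m dV/dt = (V_r - V) + I_ex - I_in,

with a spike and reset to ``V_r`` when ``V`` crosses ``V_th``.  Each
presynaptic spike makes the corresponding synaptic drive jump instantaneously
(by ``w_i`` for excitatory synapse i, by ``w_in`` for inhibitory synapses);
between spikes both drives decay exponentially with the synaptic time
constant ``tau_s``.  The drives are measured in mV (a membrane-resistance
factor is absorbed into the weights).

The module also provides the diffusion-approximation ("Siegert") estimate of
the stationary firing rate given the input statistics, with the boundary
correction for the non-zero synaptic time constant, and the transient rate
increase caused by a single presynaptic spike.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.integrate import quad
from scipy.special import erfcx

from .spiketrains import InputEnsemble, SpikeTrain

__all__ = [
    "NeuronParams",
    "RateTheoryInputs",
    "ZETA_HALF_ABS",
    "mean_rate_theory",
    "transient_rate",
    "simulate_lif",
]

#: |zeta(1/2)|, the Riemann zeta function at 1/2 (boundary correction constant
#: for colored synaptic noise).
ZETA_HALF_ABS = 1.4603545088095868


@dataclass(frozen=True)
class NeuronParams:
    """LIF and synaptic-filter constants (defaults: standard operating point).

    tau_m : membrane time constant, ms
    v_th : spiking threshold, mV
    v_r : resting / reset potential, mV
    tau_s : synaptic time constant, ms
    w_in : fixed inhibitory synaptic strength, mV
    """

    tau_m: float = 20.0
    v_th: float = -40.0
    v_r: float = -60.0
    tau_s: float = 5.0
    w_in: float = 1.0

    def __post_init__(self):
        if not self.v_th > self.v_r:
            raise ValueError("v_th must exceed v_r")
        if not self.tau_m > self.tau_s > 0:
            raise ValueError("need tau_m > tau_s > 0")
        if self.w_in < 0:
            raise ValueError("w_in must be non-negative")

    @property
    def alpha(self) -> float:
        """Boundary shift |zeta(1/2)| * sqrt(tau_s / (2 tau_m))."""
        return ZETA_HALF_ABS * math.sqrt(self.tau_s / (2.0 * self.tau_m))


@dataclass(frozen=True)
class RateTheoryInputs:
    """Population input statistics entering the rate approximation.

    mean_w : mean excitatory weight, mV; rates in Hz.
    """

    mean_w: float
    n_ex: int = 1000
    n_in: int = 250
    r_pre: float = 10.0
    r_in: float = 10.0

    def __post_init__(self):
        if min(self.mean_w, self.n_ex, self.n_in, self.r_pre, self.r_in) < 0:
            raise ValueError("all rate-theory inputs must be non-negative")


def mean_rate_theory(inputs: RateTheoryInputs, params: NeuronParams) -> float:
    """Stationary firing rate (Hz) of the LIF neuron under Poisson input.

    Diffusion approximation: the free membrane potential is Gaussian with

        mu      = (N_ex r_pre <w> - N_in r_in w_in) tau_s        (above V_r)
        sigma^2 = (N_ex r_pre <w>^2 + N_in r_in w_in^2) tau_s^2 / tau_m

    (rates in 1/ms; ``sigma^2`` is twice the stationary membrane-potential
    variance, the normalization in which the first-passage integral below is
    standard), and the mean first-passage time from reset to threshold is

        1/r = tau_m sqrt(pi) * Int_{y_r + alpha}^{y_th + alpha} erfcx(-x) dx,

    with ``y = (V - V_r - mu)/sigma`` and the threshold/reset shift ``alpha =
    |zeta(1/2)| sqrt(tau_s/(2 tau_m))`` correcting for the colored (tau_s)
    synaptic noise.  ``erfcx(-x) = exp(x^2)(1 + erf(x))`` is evaluated in its
    numerically stable form.

    Raises
    ------
    FloatingPointError
        If the integral fails to converge to a finite value.
    """
    r_pre = inputs.r_pre / 1000.0
    r_in = inputs.r_in / 1000.0
    mu = (inputs.n_ex * r_pre * inputs.mean_w - inputs.n_in * r_in * params.w_in) * params.tau_s
    sigma2 = (
        (inputs.n_ex * r_pre * inputs.mean_w**2 + inputs.n_in * r_in * params.w_in**2)
        * params.tau_s**2
        / params.tau_m
    )
    if sigma2 <= 0:
        raise ValueError("sigma must be positive (need some synaptic input)")
    sigma = math.sqrt(sigma2)
    lb = (0.0 - mu) / sigma + params.alpha            # reset, relative to V_r
    ub = (params.v_th - params.v_r - mu) / sigma + params.alpha
    if ub > 25.0:
        # exp(x^2) overflows; the first-passage time is astronomically long
        return 0.0
    val, _ = quad(lambda x: erfcx(-x), lb, ub, limit=200)
    if not math.isfinite(val):
        raise FloatingPointError(
            f"rate integral diverged (bounds {lb:.3g}, {ub:.3g})"
        )
    rate_per_ms = 1.0 / (params.tau_m * math.sqrt(math.pi) * val)
    return 1000.0 * rate_per_ms


def transient_rate(w, elapsed, baseline: float, params: NeuronParams):
    """Postsynaptic rate (Hz) ``elapsed`` ms after a presynaptic spike.

    The arrival of a presynaptic spike of weight ``w`` (mV) transiently
    raises the firing rate above ``baseline`` by
    ``w exp(-elapsed/tau_s) / ((V_th - V_r) tau_m)`` for ``elapsed >= 0``;
    earlier times return the baseline.  Accepts scalars or arrays.
    """
    elapsed = np.asarray(elapsed, dtype=float)
    excess = (
        1000.0
        * np.asarray(w, dtype=float)
        * np.exp(-np.clip(elapsed, 0.0, None) / params.tau_s)
        / ((params.v_th - params.v_r) * params.tau_m)
    )
    out = baseline + np.where(elapsed >= 0, excess, 0.0)
    return float(out) if out.ndim == 0 else out


@njit(cache=True)
def _lif_loop(inc_ex, inc_in, dt, tau_m, tau_s, v_th, v_r, v0, record_v, v_trace):
    n_steps = inc_ex.size
    a = math.exp(-dt / tau_m)
    ds = math.exp(-dt / tau_s)
    b = tau_s / (tau_m - tau_s) * (a - ds)
    v = v0
    i_ex = 0.0
    i_in = 0.0
    spikes = np.empty(n_steps, dtype=np.float64)
    n_sp = 0
    for k in range(n_steps):
        i_ex += inc_ex[k]
        i_in += inc_in[k]
        v = v_r + (v - v_r) * a + (i_ex - i_in) * b
        i_ex *= ds
        i_in *= ds
        if v >= v_th:
            # spike placed mid-bin: after this bin's presynaptic events,
            # before the next bin's (documented tie-break)
            spikes[n_sp] = (k + 0.5) * dt
            n_sp += 1
            v = v_r
        if record_v:
            v_trace[k] = v
    return spikes[:n_sp]


def _binned_increments(trains, weights, dt, n_steps) -> np.ndarray:
    """Per-step jump totals: sum of weights of spikes falling in each dt bin."""
    inc = np.zeros(n_steps, dtype=np.float64)
    for w, tr in zip(weights, trains):
        steps = (tr.times / dt).astype(np.int64)
        steps = steps[steps < n_steps]
        np.add.at(inc, steps, w)
    return inc


def simulate_lif(
    ensemble: InputEnsemble,
    weights: np.ndarray,
    params: NeuronParams = NeuronParams(),
    dt: float = 0.1,
    duration: float | None = None,
    record_v: bool = False,
    v0: float | None = None,
):
    """Clock-driven LIF simulation with fixed synaptic weights.

    Presynaptic spikes are binned to the ``dt`` grid; the membrane and both
    synaptic drives are advanced with their exact exponential update each
    step.  Returns the postsynaptic :class:`SpikeTrain`, or a tuple
    ``(train, (times, V))`` when ``record_v`` is set.

    Parameters
    ----------
    weights : array of length ``ensemble.n_ex``, mV.
    dt : time step, ms; must satisfy ``dt <= tau_s / 10``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt > params.tau_s / 10.0 + 1e-12:
        raise ValueError("dt must not exceed tau_s / 10")
    weights = np.asarray(weights, dtype=np.float64)
    if weights.size != ensemble.n_ex:
        raise ValueError("weights length must equal the number of excitatory trains")
    duration = ensemble.duration if duration is None else min(duration, ensemble.duration)
    n_steps = int(round(duration / dt))
    inc_ex = _binned_increments(ensemble.excitatory_trains, weights, dt, n_steps)
    inc_in = _binned_increments(
        ensemble.inhibitory_trains,
        np.full(ensemble.n_in, params.w_in),
        dt,
        n_steps,
    )
    v_trace = np.empty(n_steps if record_v else 0, dtype=np.float64)
    v_start = params.v_r if v0 is None else v0
    spikes = _lif_loop(
        inc_ex, inc_in, dt, params.tau_m, params.tau_s, params.v_th, params.v_r,
        v_start, record_v, v_trace,
    )
    out = SpikeTrain(times=spikes, duration=duration) if spikes.size else SpikeTrain(
        times=np.empty(0), duration=duration
    )
    if record_v:
        return out, ((np.arange(n_steps) + 1) * dt, v_trace)
    return out
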