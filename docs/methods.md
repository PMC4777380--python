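# Methods

## Model

A leaky integrate-and-fire neuron with exponential current-based synapses:

    tau_m dV/dt = (V_r - V) + I_ex - I_in,

spike and reset to `V_r` at `V_th`.  Each presynaptic spike makes the
corresponding drive jump instantaneously (by `w_i` for excitatory synapse
`i`, by `w_in` for all inhibitory synapses); both drives decay with `tau_s`.
Drives carry mV units (the membrane resistance is absorbed into the
weights).  Defaults: `tau_m = 20 ms`, `V_th = -40 mV`, `V_r = -60 mV`,
`tau_s = 5 ms`, `N_ex = 1000`, `N_in = 250`, `w_in = 1 mV`, all input rates
10 Hz.  No refractory period beyond the reset.

Integration is clock-driven at `dt = 0.1 ms` (validated: halving `dt`
changes the output rate by < 2%).  Per step the membrane and both synaptic
drives are advanced with their exact exponential updates; input spikes are
binned to the grid and processed at the bin start, an output spike is
emitted mid-bin.  The tie-break — presynaptic events of a bin before the
bin's postsynaptic spike — is fixed and documented; at 10 Hz input rates
and `dt = 0.1 ms` collisions are too rare to affect any population
statistic.

### Stationary rate approximation

The stationary firing rate under Poisson bombardment uses the
first-passage-time (diffusion) approximation

    1/r = tau_m sqrt(pi) * Int_{y_r+alpha}^{y_th+alpha} erfcx(-x) dx,
    y = (V - V_r - mu)/sigma,
    mu      = (N_ex r_pre <w> - N_in r_in w_in) tau_s,
    sigma^2 = (N_ex r_pre <w>^2 + N_in r_in w_in^2) tau_s^2 / tau_m,
    alpha   = |zeta(1/2)| sqrt(tau_s / (2 tau_m)),

with rates in 1/ms; `sigma^2` is twice the stationary membrane-potential
variance (the normalization in which this integral is standard), and
`alpha` shifts both integration bounds to correct for the colored (tau_s)
synaptic noise.  The exact normalization of `sigma^2` (a candidate factor
1/2) was fixed by comparison with direct simulation: without the 1/2 the
approximation tracks the simulated rate to 5-10% over `<w>` in
[0.6, 1.5] mV; with it the near-threshold rates are badly under-predicted
(1.5 Hz vs 4.0 Hz simulated at `<w> = 0.6`).  `erfcx(-x) =
exp(x^2)(1+erf(x))` keeps the integrand overflow-free; when the upper bound
exceeds 25 the first-passage time is astronomical and the rate is reported
as zero.

An important feature of this operating point: the neuron is **silent** for
`<w>` below about 0.55 mV (mean drive > 8 SD below threshold) and
mean-driven above about 0.65 mV.  Between roughly 0.55 and 0.9 mV the
linear-response formula for the transient rate increase after a
presynaptic spike (the causal, w-dependent part of the drift) is only
qualitative — the simulated causal drift exceeds it by up to a factor two —
while for `<w> >~ 1.1 mV` analytic and simulated drift agree within a few
percent.  Tests that compare the two therefore do so in the suprathreshold
regime; the low-weight disagreement is intrinsic to the approximation, not
an implementation artifact.

## Plasticity rules

Four event-driven rules share the pair window `A_+ e^{-dt/tau_+}` /
`-A_- e^{dt/tau_-}`:

- **pair**: all-to-all pairing via exponential trace variables (exactly
  equivalent to pair enumeration); a nearest-neighbor variant is available.
- **triplet**: trace variables `M_pre` (incremented by `A_pre` at
  presynaptic spikes, decay `tau_pre`) and `M_post` (`A_post`, `tau_post`)
  add to `A_-` and `A_+` respectively; traces are read just before their
  own-spike increment.  `A_pre = A_post = 0` recovers the pair rule
  exactly.
- **suppression**: every spike carries an efficacy
  `1 - exp(-gap/tau_pre)` (pre) or `1 - exp(-gap/tau_post)` (post) w.r.t.
  its same-type predecessor; a pairing contributes the pair window times
  both efficacies.  The default pairing is **all-to-all with efficacies**
  (implemented by efficacy-weighted traces).  A strict nearest-neighbor
  variant exists, but at the standard operating point it admits no stable
  nontrivial fixed point of the mean weight at any `tau_+/tau_-` in
  [0.8, 1.5] — flatly inconsistent with the published population behavior
  of this rule family — whereas the all-to-all reading reproduces it; the
  all-to-all reading also matches the structure of the original
  suppression model.  Isolated spike triplets give identical responses
  under both readings.  `tau_pre, tau_post -> 0` recovers the all-to-all
  pair rule.
- **NMDAR kinetics**: receptor fractions `f_up` (driven by presynaptic
  spikes, proportional to the rest fraction), `f_dn` (postsynaptic), with
  `f_rest + f_up + f_dn = 1` conserved to machine precision; messengers
  `M_up` (incremented at postsynaptic spikes by `A_M^up f_up (1 - M_up)`)
  and `M_dn` (at presynaptic spikes by `A_M^dn f_dn (1 - M_dn)`).
  Potentiation `A_+ [M_up - theta_up]_+` applies at postsynaptic spikes and
  depression `A_- [M_dn - theta_dn]_+` at presynaptic spikes, both
  evaluated *after* the same-spike messenger update; receptor and messenger
  increments use pre-spike values.  For the amplitude-ratio sweep the
  thresholds are `theta_dn = 0.2`, `theta_up = 0` (depression gated,
  potentiation not): this assignment produces the published fixed-point
  structure (a stable/unstable pair annihilating as `A_+/A_-` grows); the
  opposite assignment produces no nontrivial fixed points at all in the
  swept range.

Numba kernels implement the population-scale versions; they are validated
to machine precision against the pure-Python per-synapse reference state
machines on random spike sequences.

Bounds: *hard* clips weights to `[0, w_max]`; *soft* scales every
potentiation contribution by `1 - w/w_max` and every depression
contribution by `w/w_max` (for the triplet rule this scales the trace
contributions too, as they enter the same totals).  `w_max` defaults to
1.0 mV — initial weights uniform in [0.3, 0.7] mV then put the relevant
fixed points at interior fractions of the range — and every experiment can
override it (the suppression analyses use larger ceilings because that
rule's stable fixed points sit at 1-3 mV).

Induction protocols (`triplet_protocol_response`) repeat the three-spike
pattern 60 times at 1 s intervals, the standard experimental design; for
the linear rules this simply scales the single-triplet response, for the
thresholded NMDAR rule the repetition is what carries the messengers across
their thresholds.

## Drift estimation

*Analytic* (pair, triplet): baseline terms built from the rate
approximation plus the linear-response causal term; implemented exactly as
the closed forms.

*Frozen-weight simulation* (all rules): weights pinned, the LIF and the
rule co-simulated, candidate modifications accumulated but never applied;
the per-synapse time averages give the drift and its standard error across
synapses (synapses share the postsynaptic train, so this error bar is
mildly optimistic; it matches the convention of drift error bands in this
literature).  Because frozen weights make the postsynaptic train
independent of the plasticity, estimation is two-phase: the LIF runs once,
then the accumulators replay the merged event stream.  Two consequences are
exploited heavily:

- **Batched sweeps.** The suppression rule's pairing structure and
  efficacies do not depend on `tau_+`, so one replay accumulates
  potentiation for a whole grid of `tau_+` values.  The NMDAR rule's
  drift is `A_-(rho P(w) - D(w))` with `rho = A_+/A_-` and `P`, `D` the
  thresholded messenger sums per unit time, so a single set of frozen runs
  yields the drift curve for every amplitude ratio by linearity.
- **Shifted-control variance reduction.** The w-dependent (self-causation)
  part of the NMDAR drift is two orders of magnitude smaller than the
  between-synapse scatter, because the receptor/messenger kinetics
  (300-600 ms) barely resolve millisecond pre-post timing.  Replaying the
  same presynaptic trains against a circularly time-shifted copy of the
  post train removes all shared pre-train variance without biasing group
  differences (the shifted baseline is weight-independent); probe-synapse
  finite differences on the control-subtracted accumulators gain a factor
  ~10-25 in precision.  The estimator was validated on the pair rule,
  where the closed-form deviation rate (5.0e-4 per s at these parameters)
  is recovered within errors.

Probe design: symmetric groups of 300 synapses at +/-30% of the mean weight
(a +/-10% design with 100 probes is statistically unidentifiable for the
slow NMDAR kinetics; the larger contrast was checked for linearity on the
pair rule).  Fixed points on simulated curves require the drift to differ
from zero by >= 2 SE on both sides of a sign change; unresolved sign
changes are flagged, not counted.  Default frozen-run length is 200 s per
point, extended where the detection target demands it (the sweeps use
300-1600 s per point; the NMDAR amplitude sweep pools 3-4 independent
repetitions).  The NMDAR w-drift sign-change ratio is located by a
least-squares line through the w-dependent drift along the stable branch —
pointwise sign flips are probe-noise-dominated as the fixed point migrates
across the weight grid.

## Population experiments and classification

Full runs co-simulate the LIF and the rule with weights evolving under a
bounds policy, in 100 s input chunks (plasticity traces restart at chunk
boundaries; a sub-permille effect for traces of at most ~600 ms).  The mean
weight and group means are recorded every 1 s.  Steady state requires the
mean-weight drift over the last 20% of the run to stay below 1% of `w_max`
per 100 s; otherwise the run is extended once by 50% with a warning.

**Reduced-scale convention.** Multiplying all mV amplitudes (`A_+`, `A_-`,
`A_pre`, `A_post`) by a common factor leaves every fixed point of the mean
weight in place while speeding the weight dynamics by that factor; it
raises the diffusion-to-drift ratio, so classification experiments use
modest factors (1-10; up to 50 only for the NMDAR rule, whose thresholded
dynamics need help igniting from mid-range weights) and horizons of
1500-20000 simulated seconds.  Distribution-stability classification is run
on uncorrelated input from an active initial condition (uniform
[0.5, 0.9] mV; below ~0.55 mV the neuron is silent and nothing evolves),
while competition runs use the standard correlated probe (c = 0.2 in half
the inputs, initial weights [0.3, 0.7] mV).

**Distribution classes.** `unstable_at_bound`: >= 90% of weights within 10%
of `w_max`.  The window is 10%, not a few percent, because the depression
shot noise of these rules maintains an intrinsic boundary layer below the
bound — measured at unscaled amplitudes, a fully pinned pair-rule
population keeps only ~71% of weights within 5% of the bound but ~92%
within 10%.  Otherwise a reflected kernel-density estimate with a fixed
bandwidth of `0.04 w_max` counts prominent modes (prominence >= 5% of the
density maximum): two or more modes = `partially_stable_bimodal`, one =
`stable_unimodal`.  Silverman bandwidths over-smooth the wide, shallow
U-shapes these simulations produce; the fixed bandwidth was calibrated on
synthetic unimodal, two-pile, bowl and boundary-pile shapes.  The
classifier assumes a settled distribution (a transiently flat distribution
can read as multimodal).

**Competition classes.** With both groups present: `hebbian` if the
correlated-minus-uncorrelated mean gap is positive, statistically
significant (Welch test at alpha = 0.01) and at least 2% of `w_max` (two
saturated piles hugging the bound differ by rounding, not competition), and
the distribution is not `unstable_at_bound`; `anti_hebbian` for the
significant opposite sign; `none` otherwise.

## Known limitations and open discrepancies

- The closed-form drift is unreliable for `<w>` in the silent and
  threshold regimes (see above); the frozen-weight estimator is
  authoritative there.
- The NMDAR fixed-point annihilation ratio from direct simulation is
  ~0.076, roughly 1.8x the value a fully factorized mean-field chain gives
  (~0.038-0.042, reproduced in-package by thresholding mean messenger
  levels at Eq-8 rates): event-level fluctuations of `M_dn` around its
  threshold raise the effective depression.  The simulated value is
  reported unmodified.
- The suppression rule's original fitted parameters sit on a knife edge
  (`A_+ tau_+ = 0.173` vs `A_- tau_- = 0.176` mV·ms); direct simulation
  yields a shallow stable fixed point near 0.75 mV rather than an
  unconditional run-away, and the correlated-input probe of the
  suppression rule comes out Hebbian, not anti-Hebbian, at every tested
  combination of pairing scheme, ceiling, amplitude scale and correlation
  level: the causal potentiation advantage of synchronous volleys
  dominates the efficacy-suppression penalty at this operating point.
- Correlated groups are built by thinning one parent train, so all
  correlation is concentrated in exact zero-lag synchrony (volleys of
  ~`c N_corr` simultaneous spikes); temporally jittered correlations are
  out of scope.
- The drift-estimate standard error across synapses ignores the shared
  post-train covariance; fixed-point brackets quote grid intervals, not
  point estimates, to stay honest about resolution.
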