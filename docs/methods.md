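# Methods

## Model

`iwavesim` simulates a patch of primary motor cortex (1 mm² surface, 2.3 mm
deep) as a network of leaky integrate-and-fire point neurons organised into
eight groups: excitatory (E) and inhibitory (I) populations in layers 2/3, 4,
5 and 6, with 38,556 neurons at full scale (2/3E 10,332; 2/3I 2,916; 4E
2,412; 4I 540; 5E 10,944; 5I 2,736; 6E 7,200; 6I 1,476).

Each neuron obeys

    dV/dt     = -(V - V_r)/tau_m + I_syn/C_m
    dI_syn/dt = -I_syn/tau_syn

with C_m = 250 pF, threshold θ = -50 mV, reset V_r = -65 mV, tau_m = 10 ms,
tau_syn = 0.5 ms and an absolute refractory period tau_ref = 2 ms during
which V is clamped at V_r (synaptic current keeps integrating, so input
arriving during refractoriness is not lost).  A presynaptic spike increments
the target's I_syn by g·w after the conduction delay, with w = 87.8 pA,
g_e = +1 for excitatory sources and g_i = -4 for inhibitory sources.

### Connectivity

The number of synapses between each ordered (target, source) group pair
follows Peters' rule,

    K = log(1 - C_a) / log(1 - 1/(N_pre·N_post)),

rounded to nearest, where C_a is the pairwise connection probability table.
K counts synapses, not connected pairs: autapses are excluded, multapses
allowed.  The full-scale tables give 160,966,761 synapses, a mean of 4,174.9
per neuron (the source publication prints 4,176; the printed tables cannot
reproduce that integer exactly) and group-mean in-degrees between roughly
2,400 and 5,900.

Individual synapses are drawn by rejection sampling with Gaussian acceptance
in lateral distance, exp(-(Δx² + Δy²)/(2r²)) — depth is ignored, matching
the stated law.  Radii by connection class: excitatory intralaminar 300 µm
(layer 6: 225 µm), excitatory interlaminar ("vertical") 50 µm, inhibitory
sources always 175 µm.  Boundaries are open: edge neurons simply have fewer
near neighbours.  Conduction delays are normal with mean 1.5 ms (excitatory)
or 0.8 ms (inhibitory), SD = 50% of the mean, clipped below at one
integration step and rounded to the 0.1 ms grid.  Neuron positions are
uniform in x, y and uniform in z within each group's layer band; the band
partition of the 2.3 mm thickness — 2/3: (0, 0.9], 4: (0.9, 1.2],
5: (1.2, 1.8], 6: (1.8, 2.3] mm — is a model choice proportioned to human
M1 laminar fractions (only the total thickness is constrained).

### Input and integration

Every cortical neuron receives aggregated Poisson background: one count per
0.1 ms step with mean K_ext·(8 Hz)·dt, K_ext = 2,000 for neurons in
excitatory groups and 1,850 in inhibitory groups, each count adding g_e·w to
I_syn (statistically identical to that many independent 8 Hz fibres).  The
membrane/synapse pair is linear between spikes and is advanced with its
exact exponential propagator per 0.1 ms step; a forward-Euler mode is
retained behind `sim.integrator` for sensitivity checks, and a dt/100 Euler
integration is the independent oracle in the test suite.  Threshold
crossings are detected at step boundaries and spike times recorded at the
end of the step.  Initial potentials are drawn uniformly from [V_r, θ) to
avoid artificial synchrony (configurable to V_r for deterministic tests);
simulations run 250 ms with the first 50 ms discarded.

Runs are reproducible from two seeds: a structure seed (positions,
connection sampling, delays) and a dynamics seed (initial voltages,
background, stimulus target selection), so one network instance can be
re-stimulated under many protocols, including via its persisted connectome
(CSV or HDF5; the CSV round trip is bit-exact).

### TMS

A pulse is a one-step rectangular current injected at its onset into a
uniform random subset (`proportion`, default 0.25) of the target population,
depositing charge A(z)·dt, where A(z) falls linearly with depth from the
surface amplitude to `depth_floor` of it at 2.3 mm.  PA-direction pulses
target cortical neurons; AP-direction pulses target only a premotor afferent
group (2,000 excitatory neurons at full scale, no background drive, 2,600
efferent synapses each, 90% onto layer 2/3 and 10% onto 5E, delay
2.0 ± 50% ms).  The premotor parameters are engineering choices made to
reproduce the delayed, low-amplitude AP response qualitatively; they are all
configuration fields.  Stimulus strength is varied through `proportion`;
amplitude (default 300,000 pA) and depth floor (default 0.3) were calibrated
once so that a default PA pulse recruits roughly 60% of layer-5E neurons
within 10 ms, the activation fraction reported for the modelled experiments,
and are not re-tuned per experiment.

### Analysis

Population rates are per-step spike counts divided by (group size · dt), in
Hz per neuron, smoothed with a Gaussian kernel of SD 0.15 ms (truncated at
4 SD, renormalised; integral-conserving to <0.1%).  Waves are local maxima
of the smoothed layer-5E rate within 10 ms of the pulse exceeding a
baseline-relative threshold (mean + 3 SD of the 50 ms pre-pulse window) with
minimum separation 0.8 ms; the first peak within 0.5 ms of onset is labelled
D, later peaks I1, I2, …  The threshold multiplier, separation and window
are detection choices, exposed as arguments; detection is invariant to
uniform rate rescaling.  Wave amplitude is the smoothed peak rate (not the
burst area).  The silent period is measured on a coarsely smoothed (SD 2 ms)
pooled excitatory rate: the time from the end of the evoked burst
(onset + 10 ms) until first recovery to 50% of the pre-pulse baseline mean;
absent if the rate is never suppressed below that level.  The "sustained
oscillation" flag for runaway circuits requires an above-threshold peak in
every 5 ms sub-window of the 50 ms after the pulse.

## Reduced-scale operation

Tests and the acceptance script run reduced instances: group sizes scaled by
s (largest-remainder rounding so totals are stable), K recomputed from the
C_a table at the reduced sizes — preserving connection-probability
semantics — and the premotor group scaled alongside.  Because per-neuron
in-degrees then shrink ∝ s while the background stays fixed, a bare reduced
model leaves the full model's operating regime.  Three documented
compensation conventions are provided:

* **fluctuation** (default): recurrent weights × 1/√s preserve the variance
  of the summed asynchronous input; the deficit in its mean is restored by a
  per-neuron DC current computed from per-group reference rates (the
  standard downscaling for stationary statistics).  Reference rates are
  obtained by damped fixed-point iteration (`calibrate_reference_rates`):
  simulate, measure group rates, update with damping 0.8 (the balanced
  network's loop gain makes the undamped map oscillate), repeat ~12 times
  and average the last four iterates.  The 5E estimate is stable at
  10.4–10.9 Hz across s = 0.2–0.5.
* **linear**: recurrent weights × 1/s preserve the *mean* recurrent drive
  and the amplitude of synchronous volleys, at the cost of √(1/s)-inflated
  fluctuations that hyperpolarise and over-excite the resting state; useful
  for isolated volley-propagation studies.
* **none**: the tables taken literally at the reduced size.

Background and premotor drive are scale-invariant by construction and are
never compensated.  Problem sizes used: unit and property suites build at
s = 0.05 (~2,000 neurons, ~6.6·10⁵ synapses; seconds); the acceptance tests
at s = 0.25 and the acceptance script at s = 0.4 (~16,000 neurons,
~2.8·10⁷ synapses; a few minutes end-to-end on one CPU).  A full-scale
build needs ~5 GB and several minutes and is exercised through the same code
paths.

## What the reduced model does and does not show

Passing tests at reduced scale demonstrate that the construction rules,
integration, stimulation and analysis implement the stated model exactly
(structural counts are bit-exact at every scale), and that the compensated
reduced dynamics sit in a realistic balanced regime.  They do not guarantee
full-scale dynamical equivalence: synchronous evoked volleys scale with
√s under fluctuation compensation, so late, marginal waves are harder to
evoke at reduced scale than at full scale.

## Known limitations and divergences from the reference behaviour

Re-deriving the model from its published tables reproduces some reference
results and not others; where it does not, the package reports what it
computes rather than the published number:

* Layer-5E resting rate converges to ≈10.5 Hz (reference: 10.5 Hz), but
  layer-2/3E converges to ≈0.6–1.1 Hz rather than the reference 3.2 Hz:
  under the printed connectivity (including strong 2/3I→2/3E and 4I→2/3E
  inhibition), layer 2/3E is nearly silenced at rest.  The discrepancy
  persists near full scale (s = 0.8 uncompensated) and under both
  compensation conventions, so it reflects the printed parameterisation as
  implemented here, not a scaling artefact.
* The evoked response robustly shows a D-wave and a large I1, with I1
  delayed ~2.5 ms by the combination of refractoriness of directly activated
  5E neurons and fast feedforward inhibition.  Later waves (I2, I3) — which
  in the reference arise from a synchronized rebound of layer 2/3 — are
  largely absent, consistent with the hyperpolarised 2/3E state above: a
  rebound requires layer 2/3 to sit near threshold at rest.  Downstream
  quantities that depend on late waves (I3 recruitment threshold,
  inhibition-induced late-wave suppression, refractory-period wave rhythm)
  therefore cannot be reproduced under this parameterisation and are
  reported as measured.
* The cortical silent period (~35–90 ms depending on seed and stimulus
  calibration) and the paired-pulse facilitation (larger early waves, one
  extra wave) are qualitatively reproduced.  The published opposite-direction
  shifts of *late* waves under excitatory/inhibitory delay changes cannot be
  assessed in a response whose only indirect wave is I1; in this model I1
  simply follows the excitatory conduction delay.
* No spinal/neuromuscular stage, no conductance synapses, no neuron
  morphology, no electromagnetic field model: TMS is a current injection
  into point neurons by design.
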