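# iwavesim

A spiking-network model of motor-cortex circuitry and its response to
transcranial magnetic stimulation (TMS), for computational neuroscientists
studying how cortical circuits generate the high-frequency descending
volleys ("I-waves") recorded from the corticospinal tract after a pulse over
M1.

The model is a laminar network of 38,556 leaky integrate-and-fire neurons
(excitatory and inhibitory groups in layers 2/3, 4, 5 and 6, in a
1 mm² × 2.3 mm volume) with over 1.6·10⁸ synapses.  Membrane and synaptic
dynamics follow

    dV/dt = -(V - V_r)/τ_m + I_syn/C_m,      dI_syn/dt = -I_syn/τ_syn,
    I_syn(t + d) += g·w   when a presynaptic neuron crosses threshold,

synapse numbers per group pair follow Peters' rule
K = log(1−C_a)/log(1−1/(N_pre·N_post)), and individual connections are
placed with a Gaussian lateral-distance probability exp(−d²/2r²).  TMS is a
depth-attenuated current injection into a random 25% of neurons (PA
direction) or into a premotor afferent group (AP direction).  I-waves are
read out as peaks of the smoothed layer-5E population rate.  Full model
description: [docs/methods.md](docs/methods.md).

## Worked example

Build a reduced instance (25% of full size, proportions preserved, synapse
counts recomputed from the connection probabilities), calibrate the
reduced-scale compensation, and apply a PA pulse at 150 ms:

```python
import iwavesim as iw

cfg = iw.ModelConfig().scaled(0.25)
conn = iw.build_network(cfg)                      # ~10^7 synapses, ~20 s
cfg, rates = iw.calibrate_reference_rates(cfg, conn=conn)
print({g: round(r, 1) for g, r in rates.items()})

rec = iw.run(conn, cfg, iw.make_protocol("pa_single", cfg), dynamics_seed=7)
trace = iw.smooth(iw.population_rate(rec, "5E"))
waves = iw.detect_waves(trace, cfg.tms.onset_ms)
for w in waves.waves:
    print(f"{w.label}: t = {w.time_ms:.1f} ms, {w.amplitude_hz:.0f} Hz")
print("silent period:", iw.silent_period(rec, pulse_onset_ms=150.0), "ms")
```

prints (seed 7):

```
{'2/3E': 2.7, '2/3I': 5.9, '4E': 5.0, '4I': 7.6, '5E': 8.9, '5I': 10.2, '6E': 3.3, '6I': 9.0}
D: t = 150.1 ms, 656 Hz
I1: t = 152.7 ms, 515 Hz
silent period: 90.0 ms
```

The calibrated resting rates estimate the full-scale stationary state
(layer 5E ≈ 9–11 Hz).  The pulse evokes a D-wave at the stimulus (direct
activation of layer-5 neurons, here 656 Hz per-neuron population rate) and
an I1-wave ~2.5 ms later (trans-synaptic activation through layer 2/3),
followed by tens of milliseconds of suppressed excitatory firing — the
cortical silent period.  Note that under this parameterisation layer 2/3E is
nearly silent at rest and later I-waves (I2/I3) are largely absent; see the
"Known limitations" section of the methods note before interpreting
late-wave statistics.

A command-line interface mirrors the library:

```sh
iwavesim build --scale 0.1 --out net/
iwavesim simulate --connectome net/ --protocol pa_single --proportion 0.25 --seed 7 --out run/
iwavesim experiment run refractory_sweep --scale 0.1 --seeds 1,2,3 --out sweep.csv
```

Built-in experiments (`iwavesim experiment list`): strength sweep,
inhibition ×1.4, refractory and delay sweeps, paired pulse, PA vs AP,
minimal three-population circuits, layer-4/6 knockouts, randomised topology.

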