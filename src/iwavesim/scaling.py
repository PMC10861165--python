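"""Reduced-scale compensation for asynchronous (resting-state) statistics.

Downscaling the network shrinks per-neuron in-degrees in proportion to the
scale s.  Multiplying recurrent weights by 1/sqrt(s) preserves the variance
of the summed recurrent input, and the remaining deficit in its *mean* is
restored by a per-neuron DC current

    I_dc(t) = sum_s (D_full(t,s) * w_s - D_scaled(t,s) * w_s') * r_s * tau_syn,

where D(t,s) are in-degrees (synapses per target-group-t neuron from source
group s), w_s the full-scale signed weight, w_s' the compensated weight
actually built, and r_s reference stationary rates of the source groups.
This is the standard correction for studying the stationary state of a
downscaled asynchronous network; it requires the reference rates, which
:func:`calibrate_reference_rates` obtains by fixed-point iteration — run the
reduced model, measure group rates, recompute the DC term, repeat.

The correction deliberately targets stationary statistics: synchronous
evoked volleys scale with the *mean* per-volley drive and are the domain of
the "linear" (1/s) compensation mode instead.
"""

from __future__ import annotations

import numpy as np

from .config import FULL_SCALE_COUNTS, GROUP_NAMES, GROUP_SIGNS, ModelConfig
from .network import Connectome, build_network, compute_synapse_count

__all__ = [
    "full_scale_in_degrees",
    "dc_compensation",
    "calibrate_reference_rates",
]


def full_scale_in_degrees(config: ModelConfig) -> np.ndarray:
    """(target, source) synapses per target neuron at full scale."""
    prob = config.connectivity.prob_matrix
    n = np.array([FULL_SCALE_COUNTS[g] for g in GROUP_NAMES], dtype=float)
    deg = np.zeros_like(prob)
    for t in range(len(GROUP_NAMES)):
        for s in range(len(GROUP_NAMES)):
            deg[t, s] = compute_synapse_count(
                prob[t, s], int(n[s]), int(n[t])) / n[t]
    return deg


def dc_compensation(config: ModelConfig, conn: Connectome) -> np.ndarray:
    """Per-neuron DC current (pA) restoring the full-scale mean recurrent input.

    Zero when no reference rates are configured or at full scale.  Premotor
    neurons (silent at rest) contribute nothing and receive nothing.
    """
    n_neurons = conn.n_neurons
    if config.reference_rates is None or config.scale >= 1.0:
        return np.zeros(n_neurons)
    rates = np.array([config.reference_rates.get(g, 0.0) for g in GROUP_NAMES])
    p = config.neuron
    w_signed = np.array([p.g_e * p.w if GROUP_SIGNS[g] == "excitatory"
                         else p.g_i * p.w for g in GROUP_NAMES])
    tau_s = p.tau_syn * 1e-3
    comp = conn.meta.get("weight_compensation", 1.0)

    deg_full = full_scale_in_degrees(config)
    pair = conn.pair_counts()[:len(GROUP_NAMES), :len(GROUP_NAMES)].astype(float)
    n_scaled = conn.group_counts[:len(GROUP_NAMES)].astype(float)
    deg_scaled = pair / n_scaled[:, None]

    # mean current deficit per target group (pA)
    mu_full = (deg_full * w_signed[None, :] * rates[None, :]).sum(axis=1) * tau_s
    mu_scaled = (deg_scaled * (w_signed * comp)[None, :]
                 * rates[None, :]).sum(axis=1) * tau_s
    deficit = mu_full - mu_scaled

    dc = np.zeros(n_neurons)
    for gid in range(len(GROUP_NAMES)):
        dc[conn.group_of == gid] = deficit[gid]
    return dc


def calibrate_reference_rates(config: ModelConfig, n_iter: int = 12,
                              dynamics_seed: int = 0, damping: float = 0.8,
                              tail: int = 4, backend: str = "numba",
                              conn: Connectome | None = None):
    """Fixed-point iteration for the reference rates of "fluctuation" mode.

    Runs the reduced network without stimulation, measures per-group rates
    over the analysis window, damps the update (the loop gain of the balanced
    network makes the undamped map oscillate), and repeats; the returned
    rates average the last ``tail`` damped iterates to smooth out any
    residual limit cycle.  Returns (config, rates): a copy of ``config`` with
    ``reference_rates`` set, and the final rate mapping (an estimate of the
    full-scale resting state).
    """
    from .analysis import resting_rate
    from .engine import run

    cfg = ModelConfig.from_dict(config.to_dict())
    cfg.compensation = "fluctuation"
    if conn is None:
        conn = build_network(cfg)
    window = cfg.sim.duration - cfg.sim.analysis_start
    rates = dict(cfg.reference_rates or {})
    history = []
    for it in range(n_iter):
        cfg.reference_rates = rates or None
        record = run(conn, cfg, [], dynamics_seed=dynamics_seed + it,
                     backend=backend)
        measured = {g: resting_rate(record, g, window_ms=window)
                    for g in GROUP_NAMES}
        if rates:
            rates = {g: damping * rates[g] + (1 - damping) * measured[g]
                     for g in GROUP_NAMES}
        else:
            rates = measured
        history.append(dict(rates))
    tail = max(1, min(tail, len(history)))
    rates = {g: float(np.mean([h[g] for h in history[-tail:]]))
             for g in GROUP_NAMES}
    cfg.reference_rates = rates
    return cfg, rates
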