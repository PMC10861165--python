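"""LIF network integration with delayed synaptic delivery and Poisson drive.

The membrane/synapse pair is linear between spikes,

    dV/dt = -(V - V_r)/tau_m + I_syn/C_m,
    dI_syn/dt = -I_syn/tau_syn,

so each dt step is advanced with the exact exponential propagator of the pair
(a forward-Euler variant is kept behind ``sim.integrator`` for sensitivity
checks).  Threshold crossings are detected at step boundaries; a spike resets
V to V_r, clamps it there for the refractory period (synaptic current keeps
evolving, so input arriving during refractoriness is not lost), and schedules
``g*w`` increments on every efferent synapse at spike_time + delay via a ring
buffer.

Background drive is aggregated per neuron per step as one Poisson count with
mean K_ext * rate * dt — statistically identical to K_ext independent fibres
and far cheaper.  All randomness is consumed from numpy Generators outside
the compiled kernel, so runs are exactly reproducible from (connectome,
seeds, stimuli).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .config import GROUP_SIGNS, ModelConfig
from .network import Connectome

__all__ = [
    "SpikeRecord",
    "propagator_coefficients",
    "background_mean_counts",
    "draw_external_input",
    "run",
]


@dataclass
class SpikeRecord:
    """(neuron id, spike time) events plus the labels needed to analyse them."""

    neuron: np.ndarray       # (n_spikes,) int64
    time_ms: np.ndarray      # (n_spikes,) float64, on the dt grid
    group_names: list
    group_counts: np.ndarray
    group_of: np.ndarray
    dt: float
    duration_ms: float
    meta: dict = field(default_factory=dict)

    @property
    def n_spikes(self) -> int:
        return int(self.neuron.shape[0])

    @property
    def n_neurons(self) -> int:
        return int(self.group_of.shape[0])

    def group_indices(self, name: str) -> np.ndarray:
        gid = self.group_names.index(name)
        off = np.concatenate(([0], np.cumsum(self.group_counts)))
        return np.arange(off[gid], off[gid + 1], dtype=np.int64)

    def group_mask(self, names) -> np.ndarray:
        if isinstance(names, str):
            names = [names]
        gids = [self.group_names.index(n) for n in names]
        return np.isin(self.group_of[self.neuron], gids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"neuron_id": self.neuron, "time_ms": self.time_ms})


def propagator_coefficients(config: ModelConfig) -> tuple[float, float, float]:
    """Per-step affine update coefficients (a_m, b_i, c_s).

    exact:  V <- V_r + (V-V_r)e^{-dt/tau_m} + I*P,  I <- I e^{-dt/tau_syn},
    with P the exact cross-term of the linear pair; euler: first-order
    forward differences.  Units: ms, pF, pA, mV (pA*ms/pF = mV).
    """
    p = config.neuron
    dt = config.sim.dt
    if config.sim.integrator == "euler":
        return (1.0 - dt / p.tau_m, dt / p.C_m, 1.0 - dt / p.tau_syn)
    e_m = np.exp(-dt / p.tau_m)
    e_s = np.exp(-dt / p.tau_syn)
    if abs(p.tau_m - p.tau_syn) < 1e-12:
        cross = dt * e_m / p.C_m
    else:
        cross = (e_m - e_s) * p.tau_m * p.tau_syn / ((p.tau_m - p.tau_syn) * p.C_m)
    return (float(e_m), float(cross), float(e_s))


def background_mean_counts(config: ModelConfig, conn: Connectome) -> np.ndarray:
    """Per-neuron mean Poisson arrivals per step: K_ext * rate * dt.

    Neurons in excitatory groups get k_ext_exc fibres, inhibitory groups
    k_ext_inh; neurons with background masked off (premotor, ablated groups)
    get zero.
    """
    ext = config.external
    dt_s = config.sim.dt * 1e-3
    lam = np.zeros(conn.n_neurons)
    for gid, name in enumerate(conn.group_names):
        sel = conn.group_of == gid
        if name in GROUP_SIGNS:
            k = ext.k_ext_exc if GROUP_SIGNS[name] == "excitatory" else ext.k_ext_inh
            lam[sel] = k * ext.rate_hz * dt_s
    lam[~conn.background_mask] = 0.0
    return lam


def draw_external_input(lam: np.ndarray, n_steps: int, rng) -> np.ndarray:
    """(n_steps, N) Poisson background spike counts (uint16)."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if np.all(lam == 0):
        return np.zeros((n_steps, lam.shape[0]), dtype=np.uint16)
    return rng.poisson(lam, size=(n_steps, lam.shape[0])).astype(np.uint16)


def _synapse_csr(conn: Connectome, dt: float):
    """Synapse arrays grouped by presynaptic neuron (CSR layout)."""
    d_steps = np.rint(conn.delay_ms.astype(np.float64) / dt).astype(np.int32)
    if conn.n_synapses and d_steps.min() < 1:
        raise ValueError("all delays must be at least one integration step")
    return _kernels.csr_from_pairs(
        conn.pre.astype(np.int32, copy=False), conn.post.astype(np.int32, copy=False),
        conn.weight.astype(np.float32, copy=False), d_steps, conn.n_neurons)


def _run_numpy(V, I_syn, ref, n_steps, a_m, b_i, c_s, V_r, theta, n_ref,
               indptr, syn_post, syn_w, syn_d, bg, bg_w, dc_dv,
               inj_step, inj_neuron, inj_dv, ring_len, record_voltages):
    """Pure-numpy mirror of the compiled kernel (small instances / oracles)."""
    n = V.shape[0]
    ring = np.zeros((ring_len, n))
    sp_n, sp_t = [], []
    delivered = scheduled = 0
    ip, n_inj = 0, len(inj_step)
    v_trace = np.empty((n_steps, n)) if record_voltages else None
    for t in range(n_steps):
        slot = t % ring_len
        I_new = I_syn + ring[slot] + bg[t] * bg_w
        ring[slot] = 0.0
        refractory = ref > 0
        V[:] = np.where(refractory, V_r,
                        V_r + (V - V_r) * a_m + I_new * b_i + dc_dv)
        ref[refractory] -= 1
        I_syn[:] = I_new * c_s
        while ip < n_inj and inj_step[ip] == t:
            i = inj_neuron[ip]
            if ref[i] == 0:
                V[i] += inj_dv[ip]
            ip += 1
        spiking = np.flatnonzero((V >= theta) & (ref == 0))
        for i in spiking:
            sp_n.append(i)
            sp_t.append(t + 1)
            V[i] = V_r
            ref[i] = n_ref
            for k in range(indptr[i], indptr[i + 1]):
                arr = t + 1 + syn_d[k]
                scheduled += 1
                if arr < n_steps:
                    delivered += 1
                    ring[arr % ring_len, syn_post[k]] += syn_w[k]
        if record_voltages:
            v_trace[t] = V
    return (np.asarray(sp_n, dtype=np.int64), np.asarray(sp_t, dtype=np.int64),
            delivered, scheduled, v_trace)


def run(conn: Connectome, config: ModelConfig, stimuli=None,
        dynamics_seed=None, backend: str = "numba",
        record_voltages: bool = False) -> SpikeRecord:
    """Simulate the network for ``config.sim.duration`` ms.

    ``stimuli`` is a list of TMS pulses (see :mod:`iwavesim.stimulation`);
    target selection uses the dynamics seed so a fixed network instance can
    be re-stimulated reproducibly.  ``record_voltages`` (numpy backend only)
    attaches the full membrane-potential trace for verification work.
    """
    from .stimulation import build_injections

    config.validate()
    if dynamics_seed is None:
        dynamics_seed = config.dynamics_seed
    sim = config.sim
    n_steps = sim.n_steps
    p = config.neuron

    ss = np.random.SeedSequence(dynamics_seed)
    seed_init, seed_bg, seed_stim = ss.spawn(3)

    rng_init = np.random.default_rng(seed_init)
    if sim.init_voltage == "uniform":
        V = rng_init.uniform(p.V_r, p.theta, size=conn.n_neurons)
    else:
        V = np.full(conn.n_neurons, p.V_r, dtype=np.float64)
    I_syn = np.zeros(conn.n_neurons)
    ref = np.zeros(conn.n_neurons, dtype=np.int32)

    lam = background_mean_counts(config, conn)
    bg = draw_external_input(lam, n_steps, np.random.default_rng(seed_bg))
    bg_w = p.g_e * p.w

    inj_step, inj_neuron, inj_dv = build_injections(
        conn, config, stimuli or [], np.random.default_rng(seed_stim))

    indptr, syn_post, syn_w, syn_d = _synapse_csr(conn, sim.dt)
    ring_len = int(syn_d.max()) + 2 if conn.n_synapses else 2
    a_m, b_i, c_s = propagator_coefficients(config)
    n_ref = int(round(p.tau_ref / sim.dt))

    # standing compensation current (fluctuation-mode downscaling)
    if config.compensation == "fluctuation" and config.reference_rates:
        from .scaling import dc_compensation
        dc = dc_compensation(config, conn)
    else:
        dc = np.zeros(conn.n_neurons)
    if config.sim.integrator == "euler":
        dc_dv = dc * sim.dt / p.C_m
    else:
        dc_dv = dc * (p.tau_m / p.C_m) * (1.0 - np.exp(-sim.dt / p.tau_m))

    v_trace = None
    if backend == "numpy" or record_voltages:
        sp_n, sp_t, delivered, scheduled, v_trace = _run_numpy(
            V, I_syn, ref, n_steps, a_m, b_i, c_s, p.V_r, p.theta, n_ref,
            indptr, syn_post, syn_w, syn_d, bg, bg_w, dc_dv,
            inj_step, inj_neuron, inj_dv, ring_len, record_voltages)
    elif backend == "numba":
        sp_n, sp_t, delivered, scheduled = _kernels.lif_run(
            V, I_syn, ref, n_steps, a_m, b_i, c_s, p.V_r, p.theta, n_ref,
            indptr, syn_post, syn_w, syn_d, bg, bg_w, dc_dv,
            inj_step, inj_neuron, inj_dv, ring_len)
    else:
        raise ValueError(f"unknown backend {backend!r}")

    record = SpikeRecord(
        neuron=sp_n, time_ms=sp_t * sim.dt,
        group_names=list(conn.group_names),
        group_counts=conn.group_counts.copy(),
        group_of=conn.group_of,
        dt=sim.dt, duration_ms=sim.duration,
        meta={
            "dynamics_seed": int(dynamics_seed),
            "structure_seed": conn.meta.get("structure_seed"),
            "config_hash": config.config_hash(),
            "events_delivered": int(delivered),
            "events_scheduled": int(scheduled),
            "backend": backend,
        })
    if v_trace is not None:
        record.meta["voltage_trace"] = v_trace
    return record
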