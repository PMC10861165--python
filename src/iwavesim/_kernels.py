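"""Numba-compiled inner loops: spatial connection sampling and the LIF step loop.

Everything here is deterministic given its explicit seed / input arrays; all
randomness for the simulation loop (background counts, initial voltages,
stimulus targets) is drawn outside with numpy Generators and passed in.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def sample_pairs_gaussian(x_pre, y_pre, x_post, y_post, n_pairs,
                          inv_two_r2, same_group, seed, max_draws):
    """Draw exactly ``n_pairs`` (pre, post) index pairs by rejection sampling.

    A candidate pair (i, j) is accepted with probability
    exp(-((xi-xj)^2 + (yi-yj)^2) * inv_two_r2): the lateral-distance Gaussian
    law with z ignored.  Autapses (i == j when pre and post are the same
    group) are rejected outright; multapses are allowed.
    """
    np.random.seed(seed)
    n_pre = x_pre.shape[0]
    n_post = x_post.shape[0]
    pre = np.empty(n_pairs, np.int64)
    post = np.empty(n_pairs, np.int64)
    k = 0
    draws = 0
    while k < n_pairs:
        draws += 1
        if draws > max_draws:
            raise RuntimeError(
                "connection sampling exceeded the candidate-draw budget; "
                "radius is too small for the requested synapse count")
        i = np.random.randint(0, n_pre)
        j = np.random.randint(0, n_post)
        if same_group and i == j:
            continue
        dx = x_pre[i] - x_post[j]
        dy = y_pre[i] - y_post[j]
        p = np.exp(-(dx * dx + dy * dy) * inv_two_r2)
        if np.random.random() < p:
            pre[k] = i
            post[k] = j
            k += 1
    return pre, post


@njit(cache=True)
def sample_pairs_uniform(n_pre, n_post, n_pairs, same_group, seed):
    """Uniform (pre, post) pairs with autapses excluded; used for the
    homogenised (no spatial topology) control network."""
    np.random.seed(seed)
    pre = np.empty(n_pairs, np.int64)
    post = np.empty(n_pairs, np.int64)
    k = 0
    while k < n_pairs:
        i = np.random.randint(0, n_pre)
        j = np.random.randint(0, n_post)
        if same_group and i == j:
            continue
        pre[k] = i
        post[k] = j
        k += 1
    return pre, post


@njit(cache=True)
def csr_from_pairs(pre, post, w, d_steps, n_neurons):
    """Group the synapse table by presynaptic neuron (counting sort).

    Equivalent to a stable argsort on ``pre`` but without the int64 index
    array, which matters at full scale (~1.6e8 synapses).
    """
    n_syn = pre.shape[0]
    indptr = np.zeros(n_neurons + 1, np.int64)
    for k in range(n_syn):
        indptr[pre[k] + 1] += 1
    for i in range(n_neurons):
        indptr[i + 1] += indptr[i]
    fill = indptr[:-1].copy()
    out_post = np.empty(n_syn, np.int32)
    out_w = np.empty(n_syn, np.float32)
    out_d = np.empty(n_syn, np.int32)
    for k in range(n_syn):
        p = fill[pre[k]]
        fill[pre[k]] = p + 1
        out_post[p] = post[k]
        out_w[p] = w[k]
        out_d[p] = d_steps[k]
    return indptr, out_post, out_w, out_d


@njit(cache=True)
def lif_run(V, I_syn, ref, n_steps, a_m, b_i, c_s, V_r, theta, n_ref,
            indptr, syn_post, syn_w, syn_d,
            bg_counts, bg_w, dc_dv, inj_step, inj_neuron, inj_dv, ring_len):
    """Integrate the network for ``n_steps`` steps of width dt.

    Per step: (1) deliver due synaptic events and background counts into
    I_syn; (2) advance (V, I_syn) with the per-step affine update
    ``V <- V_r + (V - V_r)*a_m + I_syn*b_i + dc_dv``, ``I_syn <- I_syn*c_s``
    (coefficients encode either the exact exponential propagator or forward
    Euler; ``dc_dv`` is the per-step voltage contribution of any standing
    compensation current); (3) add scheduled current injections (skipped while refractory,
    where V is clamped at V_r); (4) threshold, reset, and schedule deliveries
    ``d`` steps after the spike through a ring buffer.

    Spike times are recorded at the end of the step in which threshold was
    crossed (step index t+1); a synapse with delay d*dt then increments the
    target's I_syn at exactly spike_time + delay.

    Returns (spike_neuron, spike_step, delivered, scheduled) where the last
    two count synaptic events delivered within the window vs. all scheduled.
    """
    n = V.shape[0]
    ring = np.zeros((ring_len, n))
    cap = 1024 + 8 * n
    sp_n = np.empty(cap, np.int64)
    sp_t = np.empty(cap, np.int64)
    nsp = 0
    delivered = 0
    scheduled = 0
    ip = 0
    n_inj = inj_step.shape[0]
    for t in range(n_steps):
        slot = t % ring_len
        for i in range(n):
            I_new = I_syn[i] + ring[slot, i] + bg_counts[t, i] * bg_w
            ring[slot, i] = 0.0
            if ref[i] > 0:
                ref[i] -= 1
                V[i] = V_r
            else:
                V[i] = V_r + (V[i] - V_r) * a_m + I_new * b_i + dc_dv[i]
            I_syn[i] = I_new * c_s
        while ip < n_inj and inj_step[ip] == t:
            i = inj_neuron[ip]
            if ref[i] == 0:
                V[i] += inj_dv[ip]
            ip += 1
        for i in range(n):
            if ref[i] == 0 and V[i] >= theta:
                if not np.isfinite(V[i]):
                    raise FloatingPointError(
                        "non-finite membrane potential during integration")
                if nsp >= cap:
                    cap2 = cap * 2
                    tmp_n = np.empty(cap2, np.int64)
                    tmp_t = np.empty(cap2, np.int64)
                    tmp_n[:nsp] = sp_n[:nsp]
                    tmp_t[:nsp] = sp_t[:nsp]
                    sp_n = tmp_n
                    sp_t = tmp_t
                    cap = cap2
                sp_n[nsp] = i
                sp_t[nsp] = t + 1
                nsp += 1
                V[i] = V_r
                ref[i] = n_ref
                for k in range(indptr[i], indptr[i + 1]):
                    arr = t + 1 + syn_d[k]
                    scheduled += 1
                    if arr < n_steps:
                        delivered += 1
                        ring[arr % ring_len, syn_post[k]] += syn_w[k]
    return sp_n[:nsp], sp_t[:nsp], delivered, scheduled
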