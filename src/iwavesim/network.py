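"""Construction of the laminar motor-cortex network.

Neurons are placed uniformly in a 1 mm^2 x 2.3 mm volume (x, y uniform over
the surface, z uniform within each group's layer band).  The number of
synapses between every ordered (target, source) group pair follows Peters'
rule,

    K = log(1 - C_a) / log(1 - 1/(N_pre * N_post)),

rounded to the nearest integer, where C_a is the group-to-group connection
probability.  Individual synapses are then drawn by rejection sampling with a
Gaussian acceptance probability in lateral (x, y) distance,
exp(-d^2 / (2 r^2)), with the radius r set by connection class.  Conduction
delays are normal around the class mean (SD = delay_rel_sd * mean), truncated
below at one integration step and rounded onto the dt grid.  Autapses are
excluded; multapses are allowed (Peters' rule counts synapses, not pairs).

The resulting :class:`Connectome` is an explicit synapse table
(pre, post, weight, delay) plus per-neuron group labels and positions, and
can be persisted to CSV (or HDF5) and reloaded bit-identically so a single
network instance can be re-simulated.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._kernels import sample_pairs_gaussian
from .config import (GROUP_LAYERS, GROUP_NAMES, GROUP_SIGNS, Geometry,
                     ModelConfig)

__all__ = [
    "Connectome",
    "ConstructionError",
    "ConnectomeFormatError",
    "compute_synapse_count",
    "place_neurons",
    "sample_connections",
    "assign_delays",
    "connection_radius_mm",
    "build_network",
    "save_connectome",
    "load_connectome",
]

PREMOTOR_GROUP = "PM"


class ConstructionError(RuntimeError):
    """Network construction failed (inconsistent tables, multapse cap, ...)."""


class ConnectomeFormatError(ValueError):
    """A persisted connectome table violates an invariant."""


@dataclass
class Connectome:
    """Explicit synapse list plus the neuron table it indexes into.

    Neurons are numbered contiguously group by group in canonical order
    (cortical groups first, then the optional premotor group).  ``weight`` is
    the signed synaptic current increment g*w in pA; ``delay_ms`` is aligned
    to the integration grid ``dt``.
    """

    pre: np.ndarray          # (S,) int32 presynaptic neuron index
    post: np.ndarray         # (S,) int32 postsynaptic neuron index
    weight: np.ndarray       # (S,) float32 signed increment (pA)
    delay_ms: np.ndarray     # (S,) float32 grid-aligned conduction delay
    group_names: list        # group label per group id
    group_counts: np.ndarray  # (G,) int64 neurons per group
    group_of: np.ndarray     # (N,) int16 group id per neuron
    positions: np.ndarray    # (N, 3) float64 x, y, z in mm
    dt: float                # delay grid (ms)
    background_mask: np.ndarray = None  # (N,) bool: receives Poisson drive
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.background_mask is None:
            mask = np.ones(self.n_neurons, dtype=bool)
            if PREMOTOR_GROUP in self.group_names:
                mask[self.group_of == self.group_names.index(PREMOTOR_GROUP)] = False
            self.background_mask = mask

    @property
    def n_neurons(self) -> int:
        return int(self.group_of.shape[0])

    @property
    def n_synapses(self) -> int:
        return int(self.pre.shape[0])

    @property
    def group_offsets(self) -> np.ndarray:
        return np.concatenate(([0], np.cumsum(self.group_counts)))

    def group_id(self, name: str) -> int:
        try:
            return self.group_names.index(name)
        except ValueError:
            raise KeyError(f"no neuron group named {name!r}") from None

    def group_indices(self, name: str) -> np.ndarray:
        gid = self.group_id(name)
        off = self.group_offsets
        return np.arange(off[gid], off[gid + 1], dtype=np.int64)

    def cortical_indices(self) -> np.ndarray:
        """All neurons except the premotor group."""
        if PREMOTOR_GROUP in self.group_names:
            return np.flatnonzero(
                self.group_of != self.group_names.index(PREMOTOR_GROUP))
        return np.arange(self.n_neurons, dtype=np.int64)

    def synapse_group_pair(self) -> tuple[np.ndarray, np.ndarray]:
        """(target_gid, source_gid) per synapse."""
        return self.group_of[self.post], self.group_of[self.pre]

    def pair_counts(self) -> np.ndarray:
        """(G, G) synapse counts indexed [target, source]."""
        g = len(self.group_names)
        tgt, src = self.synapse_group_pair()
        flat = np.bincount(tgt.astype(np.int64) * g + src, minlength=g * g)
        return flat.reshape(g, g)

    def neuron_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": np.arange(self.n_neurons, dtype=np.int64),
            "group": [self.group_names[g] for g in self.group_of],
            "x_mm": self.positions[:, 0],
            "y_mm": self.positions[:, 1],
            "z_mm": self.positions[:, 2],
        })

    def synapse_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pre": self.pre, "post": self.post,
            "weight_pA": self.weight, "delay_ms": self.delay_ms,
        })


# ----------------------------------------------------------------- primitives

def compute_synapse_count(C_a: float, N_pre: int, N_post: int) -> int:
    """Number of synapses between two groups under Peters' rule.

    Solves for the number of independent uniform synapse placements K such
    that the probability of a given ordered neuron pair being connected at
    least once equals ``C_a``; rounded to the nearest integer.
    """
    if not (0.0 <= C_a < 1.0):
        raise ValueError(f"connection probability must satisfy 0 <= C_a < 1, got {C_a}")
    if N_pre < 1 or N_post < 1:
        raise ValueError("group sizes must be >= 1")
    if C_a == 0.0:
        return 0
    if N_pre * N_post < 2:
        raise ValueError("Peters' rule is undefined for a single neuron pair")
    # log1p keeps full precision when 1/(N_pre*N_post) is tiny.
    k = math.log1p(-C_a) / math.log1p(-1.0 / (N_pre * N_post))
    return int(math.floor(k + 0.5))


def place_neurons(group_counts: dict, geometry: Geometry, seed) -> np.ndarray:
    """Uniform neuron positions: x, y over the surface, z within layer bands.

    ``group_counts`` maps cortical group names to counts; neurons are laid
    out contiguously in canonical group order.  Returns an (N, 3) array (mm).
    """
    geometry.validate()
    rng = np.random.default_rng(seed)
    chunks = []
    for name in GROUP_NAMES:
        n = int(group_counts[name])
        lo, hi = geometry.layer_bounds[GROUP_LAYERS[name]]
        xy = rng.uniform(0.0, geometry.side_mm, size=(n, 2))
        z = rng.uniform(lo, hi, size=(n, 1))
        chunks.append(np.hstack([xy, z]))
    return np.vstack(chunks)


def connection_radius_mm(config: ModelConfig, target: str, source: str) -> float:
    """Gaussian radius (mm) for a (target, source) group pair.

    Inhibitory sources always use the inhibitory radius; excitatory sources
    use the intralaminar radius within a layer (layer 6 has its own value)
    and the narrow vertical radius across layers.
    """
    conn = config.connectivity
    if GROUP_SIGNS[source] == "inhibitory":
        r_um = conn.radius_inhibitory_um
    elif GROUP_LAYERS[source] == GROUP_LAYERS[target]:
        r_um = (conn.radius_lateral_e_l6_um if GROUP_LAYERS[source] == "6"
                else conn.radius_lateral_e_um)
    else:
        r_um = conn.radius_vertical_e_um
    return r_um / 1000.0


def sample_connections(pos_pre: np.ndarray, pos_post: np.ndarray, n_pairs: int,
                       radius_mm: float, seed, same_group: bool = False,
                       max_multapse_factor: float = 100.0):
    """Exactly ``n_pairs`` (pre, post) local-index pairs with Gaussian
    lateral-distance acceptance (z ignored).  Autapses are excluded when the
    two position arrays describe the same group."""
    if n_pairs < 0:
        raise ValueError("n_pairs must be >= 0")
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    n_pre, n_post = len(pos_pre), len(pos_post)
    cap = max_multapse_factor * n_pre * n_post
    if n_pairs > cap:
        raise ConstructionError(
            f"requested {n_pairs} synapses exceeds the multapse cap "
            f"({max_multapse_factor} x {n_pre}*{n_post})")
    if n_pairs == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    seed = int(np.uint32(seed))
    # Candidate budget: generous multiple of the worst-case acceptance rate.
    area = 1.0  # relative; acceptance ~ 2*pi*r^2 for a unit surface
    accept_floor = min(1.0, 2.0 * np.pi * radius_mm ** 2 / max(area, 1e-9)) * 0.25
    max_draws = int(n_pairs / max(accept_floor, 1e-6) * 50 + 10_000_000)
    return sample_pairs_gaussian(
        np.ascontiguousarray(pos_pre[:, 0]), np.ascontiguousarray(pos_pre[:, 1]),
        np.ascontiguousarray(pos_post[:, 0]), np.ascontiguousarray(pos_post[:, 1]),
        n_pairs, 1.0 / (2.0 * radius_mm ** 2), same_group, seed, max_draws)


def assign_delays(n: int, mean_ms: float, rel_sd: float, dt: float, seed) -> np.ndarray:
    """Conduction delays: normal(mean, rel_sd*mean), truncated below at one
    step, rounded to the dt grid.  rel_sd = 0 gives every delay == mean."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = rng.normal(mean_ms, rel_sd * mean_ms, size=n)
    d = np.maximum(d, dt)
    return np.round(d / dt) * dt


# -------------------------------------------------------------------- build

def build_network(config: ModelConfig, structure_seed=None) -> Connectome:
    """Build the full connectome specified by ``config``.

    Reproducible: the structure seed fixes positions, connection sampling and
    delays.  Recurrent weights are multiplied by 1/scale at reduced scale when
    ``config.compensate_weights`` so the mean recurrent input per neuron is
    preserved (background and premotor drive are scale-invariant as-is).
    """
    config.validate()
    if structure_seed is None:
        structure_seed = config.structure_seed
    ss = np.random.SeedSequence(structure_seed)
    seed_place, seed_conn, seed_delay, seed_pm = ss.spawn(4)

    counts = config.counts_array
    prob = config.connectivity.prob_matrix
    if prob.shape != (len(GROUP_NAMES),) * 2:
        raise ConstructionError("connection-probability table has wrong shape")

    positions = place_neurons(config.group_counts, config.geometry, seed_place)
    offsets = np.concatenate(([0], np.cumsum(counts)))

    if config.scale < 1.0 and config.compensation == "linear":
        comp = 1.0 / config.scale
    elif config.scale < 1.0 and config.compensation == "fluctuation":
        comp = 1.0 / np.sqrt(config.scale)
    else:
        comp = 1.0
    w_exc = config.neuron.g_e * config.neuron.w * comp
    w_inh = config.neuron.g_i * config.neuron.w * comp
    dt = config.sim.dt

    pair_seeds = seed_conn.spawn(len(GROUP_NAMES) ** 2)
    delay_rng = np.random.default_rng(seed_delay)

    # Preallocate the full synapse table (int32/float32) and fill per pair:
    # keeps the peak footprint near the final table size even at full scale.
    pair_k = np.zeros((len(GROUP_NAMES), len(GROUP_NAMES)), dtype=np.int64)
    for ti in range(len(GROUP_NAMES)):
        for si in range(len(GROUP_NAMES)):
            pair_k[ti, si] = compute_synapse_count(
                prob[ti, si], int(counts[si]), int(counts[ti]))
    n_ctx_syn = int(pair_k.sum())
    n_pm_syn = (config.premotor.n * config.premotor.synapses_per_neuron
                if config.premotor.enabled else 0)
    total = n_ctx_syn + n_pm_syn
    pre = np.empty(total, np.int32)
    post = np.empty(total, np.int32)
    weight = np.empty(total, np.float32)
    delay = np.empty(total, np.float32)

    cursor = 0
    for ti, target in enumerate(GROUP_NAMES):
        for si, source in enumerate(GROUP_NAMES):
            k = int(pair_k[ti, si])
            if k == 0:
                continue
            radius = connection_radius_mm(config, target, source)
            pre_loc, post_loc = sample_connections(
                positions[offsets[si]:offsets[si + 1]],
                positions[offsets[ti]:offsets[ti + 1]],
                k, radius,
                pair_seeds[ti * len(GROUP_NAMES) + si].generate_state(1)[0],
                same_group=(ti == si),
                max_multapse_factor=config.connectivity.max_multapse_factor)
            sl = slice(cursor, cursor + k)
            pre[sl] = pre_loc + offsets[si]
            post[sl] = post_loc + offsets[ti]
            sign = GROUP_SIGNS[source]
            weight[sl] = w_exc if sign == "excitatory" else w_inh
            mean = (config.neuron.delay_e_mean if sign == "excitatory"
                    else config.neuron.delay_i_mean)
            delay[sl] = assign_delays(k, mean, config.neuron.delay_rel_sd,
                                      dt, delay_rng)
            cursor += k

    group_names = list(GROUP_NAMES)
    group_counts = counts.copy()
    group_of = np.repeat(np.arange(len(GROUP_NAMES), dtype=np.int16), counts)

    if config.premotor.enabled and config.premotor.n > 0:
        pm = config.premotor
        rng = np.random.default_rng(seed_pm)
        n_m1 = int(counts.sum())
        pm_ids = np.arange(n_m1, n_m1 + pm.n, dtype=np.int32)
        if n_pm_syn > 0:
            sl = slice(cursor, cursor + n_pm_syn)
            pre[sl] = np.repeat(pm_ids, pm.synapses_per_neuron)
            l23 = np.arange(offsets[0], offsets[2])          # 2/3E + 2/3I
            l5e = np.arange(offsets[4], offsets[5])
            to_l23 = rng.random(n_pm_syn) < pm.frac_to_l23
            post[sl] = np.where(to_l23,
                                rng.choice(l23, size=n_pm_syn),
                                rng.choice(l5e, size=n_pm_syn))
            # Premotor drive is scale-invariant by construction: never compensated.
            weight[sl] = config.neuron.g_e * config.neuron.w
            delay[sl] = assign_delays(n_pm_syn, pm.delay_mean_ms, pm.delay_rel_sd,
                                      dt, rng)
            cursor += n_pm_syn
        group_names.append(PREMOTOR_GROUP)
        group_counts = np.concatenate([group_counts, [pm.n]])
        group_of = np.concatenate([group_of,
                                   np.full(pm.n, len(group_names) - 1, np.int16)])
        # Premotor somata sit outside the modelled volume; nominal surface
        # positions keep the table rectangular.
        pm_pos = np.zeros((pm.n, 3))
        pm_pos[:, :2] = rng.uniform(0.0, config.geometry.side_mm, size=(pm.n, 2))
        positions = np.vstack([positions, pm_pos])

    assert cursor == total
    return Connectome(
        pre=pre, post=post, weight=weight, delay_ms=delay,
        group_names=group_names, group_counts=group_counts.astype(np.int64),
        group_of=group_of, positions=positions, dt=dt,
        meta={
            "scale": config.scale,
            "structure_seed": int(structure_seed),
            "weight_compensation": comp,
            "config_hash": config.config_hash(),
        })


# -------------------------------------------------------------- persistence

def _validate_tables(syn: pd.DataFrame, neu: pd.DataFrame, dt: float) -> None:
    required = {"pre", "post", "weight_pA", "delay_ms"}
    if not required.issubset(syn.columns):
        raise ConnectomeFormatError(
            f"synapse table missing column(s) {sorted(required - set(syn.columns))}")
    n = len(neu)
    bad = np.flatnonzero(syn["pre"].to_numpy() == syn["post"].to_numpy())
    if bad.size:
        raise ConnectomeFormatError(f"autapse (pre == post) at synapse row {bad[0]}")
    bad = np.flatnonzero(syn["delay_ms"].to_numpy() < dt - 1e-9)
    if bad.size:
        raise ConnectomeFormatError(
            f"delay below one integration step at synapse row {bad[0]}")
    idx = np.concatenate([syn["pre"].to_numpy(), syn["post"].to_numpy()]) \
        if len(syn) else np.empty(0, np.int64)
    if len(idx) and (idx.min() < 0 or idx.max() >= n):
        raise ConnectomeFormatError("synapse table references a neuron id "
                                    "outside the neuron table")


def save_connectome(conn: Connectome, path: str) -> None:
    """Persist to ``path``: an HDF5 file if it ends in .h5/.hdf5, otherwise a
    directory with synapses.csv, neurons.csv and meta.json."""
    if str(path).endswith((".h5", ".hdf5")):
        import h5py
        with h5py.File(path, "w") as f:
            for name, arr in (("pre", conn.pre), ("post", conn.post),
                              ("weight_pA", conn.weight),
                              ("delay_ms", conn.delay_ms),
                              ("group_of", conn.group_of),
                              ("group_counts", conn.group_counts),
                              ("positions", conn.positions),
                              ("background_mask", conn.background_mask)):
                f.create_dataset(name, data=arr)
            f.attrs["dt"] = conn.dt
            f.attrs["group_names"] = json.dumps(conn.group_names)
            f.attrs["meta"] = json.dumps(conn.meta, default=str)
        return
    os.makedirs(path, exist_ok=True)
    # %.17g guarantees bit-exact float round-trips through the text format
    conn.synapse_table().to_csv(os.path.join(path, "synapses.csv"),
                                index=False, float_format="%.17g")
    conn.neuron_table().to_csv(os.path.join(path, "neurons.csv"),
                               index=False, float_format="%.17g")
    with open(os.path.join(path, "meta.json"), "w") as fh:
        json.dump({
            "dt": conn.dt,
            "group_names": conn.group_names,
            "group_counts": conn.group_counts.tolist(),
            "background_mask_false": np.flatnonzero(~conn.background_mask).tolist(),
            "meta": conn.meta,
        }, fh, default=str)


def load_connectome(path: str) -> Connectome:
    """Inverse of :func:`save_connectome`; validates invariants row by row."""
    if str(path).endswith((".h5", ".hdf5")):
        import h5py
        with h5py.File(path, "r") as f:
            conn = Connectome(
                pre=f["pre"][:].astype(np.int32),
                post=f["post"][:].astype(np.int32),
                weight=f["weight_pA"][:].astype(np.float32),
                delay_ms=f["delay_ms"][:].astype(np.float32),
                group_names=json.loads(f.attrs["group_names"]),
                group_counts=f["group_counts"][:].astype(np.int64),
                group_of=f["group_of"][:].astype(np.int16),
                positions=f["positions"][:],
                dt=float(f.attrs["dt"]),
                background_mask=f["background_mask"][:].astype(bool),
                meta=json.loads(f.attrs["meta"]))
        _validate_tables(conn.synapse_table(), conn.neuron_table(), conn.dt)
        return conn
    with open(os.path.join(path, "meta.json")) as fh:
        info = json.load(fh)
    syn = pd.read_csv(os.path.join(path, "synapses.csv"),
                      float_precision="round_trip")
    neu = pd.read_csv(os.path.join(path, "neurons.csv"),
                      float_precision="round_trip")
    _validate_tables(syn, neu, float(info["dt"]))
    group_names = list(info["group_names"])
    name_to_id = {g: i for i, g in enumerate(group_names)}
    try:
        group_of = neu["group"].map(name_to_id).to_numpy(dtype=np.int16)
    except Exception as exc:
        raise ConnectomeFormatError(f"neuron table has an unknown group: {exc}")
    mask = np.ones(len(neu), dtype=bool)
    mask[np.asarray(info.get("background_mask_false", []), dtype=np.int64)] = False
    return Connectome(
        pre=syn["pre"].to_numpy(np.int32), post=syn["post"].to_numpy(np.int32),
        weight=syn["weight_pA"].to_numpy(np.float64).astype(np.float32),
        delay_ms=syn["delay_ms"].to_numpy(np.float64).astype(np.float32),
        group_names=group_names,
        group_counts=np.asarray(info["group_counts"], dtype=np.int64),
        group_of=group_of,
        positions=neu[["x_mm", "y_mm", "z_mm"]].to_numpy(np.float64),
        dt=float(info["dt"]),
        background_mask=mask,
        meta=dict(info.get("meta", {})))


def subset_synapses(conn: Connectome, keep: np.ndarray) -> Connectome:
    """Connectome with the same neurons but only the ``keep``-masked synapses."""
    return replace(conn,
                   pre=conn.pre[keep], post=conn.post[keep],
                   weight=conn.weight[keep], delay_ms=conn.delay_ms[keep],
                   background_mask=conn.background_mask.copy(),
                   meta=dict(conn.meta))
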