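"""Named, config-driven manipulations of the circuit and stimulation protocol.

Circuit variants are strict subgraphs of one fixed network instance: the
retained populations keep their neuron indices and every retained synapse is
bit-identical to the full model's, so differences in the evoked response are
attributable to the removed connections alone.  Removed groups also lose
their background drive (they are absent from the variant, not merely
disconnected).

The simple three-population circuits (layer 2/3E, 2/3I, 5E) follow the
classical minimal I-wave hypotheses.  "Between-group" connections are every
ordered pair of distinct groups among the trio (2/3E->5E, 2/3I->5E,
2/3E->2/3I, 2/3I->2/3E and the weak 5E->2/3 feedback); "recurrent" means
within-group:

* ``feedforward``     — between-group connections only: the E->I->E loop is
                        closed but no population feeds back onto itself.
* ``recurrent_excitation`` — plus 2/3E->2/3E and 5E->5E.
* ``recurrent_inhibition`` — plus 2/3I->2/3I (recurrent inhibition, which
                        self-limits the interneuron volley and disinhibits
                        the excitatory rebound).
* ``full_recurrent``  — all within-group connections (raises excitation and
                        lowers inhibition at once).

``no_layer4`` / ``no_layer6`` knock out whole layers of the full model;
``random_topology`` redraws the lateral (within-layer) partners uniformly
while keeping per-pair synapse counts, delays and weights, and all
interlaminar (vertical) connections untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import analysis, engine, stimulation
from ._kernels import sample_pairs_uniform
from .config import GROUP_LAYERS, GROUP_NAMES, ModelConfig
from .network import PREMOTOR_GROUP, Connectome, build_network, subset_synapses

__all__ = [
    "CircuitVariant",
    "VARIANTS",
    "build_variant",
    "randomize_topology",
    "ExperimentSpec",
    "EXPERIMENTS",
    "run_experiment",
    "run_condition",
]

_SIMPLE_GROUPS = ("2/3E", "2/3I", "5E")
_FEEDFORWARD_PAIRS = tuple(  # every between-group (target, source) pair
    (t, s) for t in _SIMPLE_GROUPS for s in _SIMPLE_GROUPS if t != s)


@dataclass(frozen=True)
class CircuitVariant:
    """Subgraph description: kept groups and kept (target, source) pairs.

    ``kept_pairs=None`` keeps every pair among the kept groups.  The premotor
    group is always retained so AP protocols remain available.
    """

    name: str
    kept_groups: tuple = GROUP_NAMES
    kept_pairs: tuple | None = None


VARIANTS = {
    "full": CircuitVariant("full"),
    "feedforward": CircuitVariant(
        "feedforward", _SIMPLE_GROUPS, _FEEDFORWARD_PAIRS),
    "recurrent_excitation": CircuitVariant(
        "recurrent_excitation", _SIMPLE_GROUPS,
        _FEEDFORWARD_PAIRS + (("2/3E", "2/3E"), ("5E", "5E"))),
    "recurrent_inhibition": CircuitVariant(
        "recurrent_inhibition", _SIMPLE_GROUPS,
        _FEEDFORWARD_PAIRS + (("2/3I", "2/3I"),)),
    "full_recurrent": CircuitVariant(
        "full_recurrent", _SIMPLE_GROUPS,
        _FEEDFORWARD_PAIRS + (("2/3E", "2/3E"), ("5E", "5E"),
                              ("2/3I", "2/3I"))),
    "no_layer4": CircuitVariant(
        "no_layer4", tuple(g for g in GROUP_NAMES if GROUP_LAYERS[g] != "4")),
    "no_layer6": CircuitVariant(
        "no_layer6", tuple(g for g in GROUP_NAMES if GROUP_LAYERS[g] != "6")),
}


def build_variant(conn: Connectome, variant: CircuitVariant) -> Connectome:
    """Restrict ``conn`` to the variant's groups and connection pairs.

    Never adds or resamples synapses; retained synapses keep their exact
    parameters.  Neurons of removed groups stay in the index space (so shared
    populations keep identical indices) but lose their background drive.
    """
    missing = [g for g in variant.kept_groups if g not in conn.group_names]
    if missing:
        raise KeyError(f"variant references missing group(s) {missing}")
    kept = set(variant.kept_groups) | {PREMOTOR_GROUP}
    kept_ids = np.array([conn.group_names.index(g) for g in kept
                         if g in conn.group_names])
    tgt, src = conn.synapse_group_pair()
    keep = np.isin(tgt, kept_ids) & np.isin(src, kept_ids)
    if variant.kept_pairs is not None:
        pair_ok = np.zeros_like(keep)
        for target, source in variant.kept_pairs:
            pair_ok |= (tgt == conn.group_id(target)) & (src == conn.group_id(source))
        # premotor efferents are not part of the cortical pair table
        if PREMOTOR_GROUP in conn.group_names:
            pair_ok |= src == conn.group_id(PREMOTOR_GROUP)
        keep &= pair_ok
    out = subset_synapses(conn, keep)
    removed = [g for g in conn.group_names
               if g not in kept and g != PREMOTOR_GROUP]
    for g in removed:
        out.background_mask[out.group_indices(g)] = False
    out.meta["variant"] = variant.name
    return out


def randomize_topology(conn: Connectome, seed) -> Connectome:
    """Homogenise lateral connectivity: within-layer partners become uniform.

    Per (target, source) pair the synapse count is preserved exactly; only
    within-layer (lateral) cortical connections are redrawn, uniformly over
    ordered neuron pairs with autapses excluded.  Vertical (interlaminar)
    connections, premotor efferents, weights and delays are untouched.
    """
    rng = np.random.default_rng(seed)
    pre = conn.pre.copy()
    post = conn.post.copy()
    off = conn.group_offsets
    tgt, src = conn.synapse_group_pair()
    for ti, target in enumerate(conn.group_names):
        for si, source in enumerate(conn.group_names):
            if target == PREMOTOR_GROUP or source == PREMOTOR_GROUP:
                continue
            if GROUP_LAYERS[target] != GROUP_LAYERS[source]:
                continue
            sel = np.flatnonzero((tgt == ti) & (src == si))
            if sel.size == 0:
                continue
            new_pre, new_post = sample_pairs_uniform(
                int(conn.group_counts[si]), int(conn.group_counts[ti]),
                sel.size, ti == si,
                int(rng.integers(0, 2**32)))
            pre[sel] = new_pre + off[si]
            post[sel] = new_post + off[ti]
    from dataclasses import replace
    return replace(conn, pre=pre, post=post,
                   weight=conn.weight.copy(), delay_ms=conn.delay_ms.copy(),
                   background_mask=conn.background_mask.copy(),
                   meta={**conn.meta, "topology": "random"})


# ------------------------------------------------------------------ running

@dataclass
class ExperimentSpec:
    """One named experiment: a list of conditions over a base configuration.

    Each condition may override neuron parameters (rebuilding the network
    when structural parameters change), pick a circuit variant or topology,
    scale inhibition, and set the stimulation protocol.
    """

    name: str
    conditions: list          # list of dicts, see _CONDITION_KEYS
    description: str = ""


_CONDITION_KEYS = {
    "label", "tau_ref", "delay_e_mean", "delay_i_mean", "proportion",
    "protocol", "interval_ms", "variant", "topology", "inhibition_factor",
}


def _builtin_experiments() -> dict:
    exps = {}
    exps["strength_sweep"] = ExperimentSpec(
        "strength_sweep",
        [{"label": f"p={p}", "proportion": p, "protocol": "pa_single"}
         for p in (0.15, 0.175, 0.2, 0.225, 0.25, 0.3, 0.4)],
        "I-wave amplitudes vs stimulated proportion (PA)")
    exps["inhibition"] = ExperimentSpec(
        "inhibition",
        [{"label": "control", "protocol": "pa_single"},
         {"label": "gaba_x1.4", "protocol": "pa_single", "inhibition_factor": 1.4}],
        "Inhibitory weight x1.4 (GABA-A agonist analogue)")
    exps["refractory_sweep"] = ExperimentSpec(
        "refractory_sweep",
        [{"label": f"tau_ref={t}", "tau_ref": t, "protocol": "pa_single"}
         for t in (1.0, 1.5, 1.75, 2.0, 2.5)],
        "Refractory period vs inter-wave interval")
    exps["excitatory_delay_sweep"] = ExperimentSpec(
        "excitatory_delay_sweep",
        [{"label": f"d_e={d}", "delay_e_mean": d, "protocol": "pa_single"}
         for d in (0.5, 1.25, 1.5, 2.0)],
        "Mean excitatory delay sweep")
    exps["inhibitory_delay_sweep"] = ExperimentSpec(
        "inhibitory_delay_sweep",
        [{"label": f"d_i={d}", "delay_i_mean": d, "protocol": "pa_single"}
         for d in (0.5, 0.75, 0.8, 1.0)],
        "Mean inhibitory delay sweep")
    exps["paired_pulse"] = ExperimentSpec(
        "paired_pulse",
        [{"label": "single", "protocol": "pa_single"},
         {"label": "paired_2ms", "protocol": "paired", "interval_ms": 2.0}],
        "Single vs paired PA pulse at 2 ms interstimulus interval")
    exps["direction"] = ExperimentSpec(
        "direction",
        [{"label": "PA", "protocol": "pa_single"},
         {"label": "AP", "protocol": "ap_single"}],
        "PA vs AP induced-current direction")
    exps["circuits"] = ExperimentSpec(
        "circuits",
        [{"label": v, "variant": v, "protocol": "pa_single"}
         for v in ("feedforward", "recurrent_excitation",
                   "recurrent_inhibition", "full_recurrent")],
        "Minimal three-population circuits")
    exps["knockouts"] = ExperimentSpec(
        "knockouts",
        [{"label": "full", "protocol": "pa_single"},
         {"label": "no_layer4", "variant": "no_layer4", "protocol": "pa_single"},
         {"label": "no_layer6", "variant": "no_layer6", "protocol": "pa_single"}],
        "Layer 4 / layer 6 knockouts")
    exps["topology"] = ExperimentSpec(
        "topology",
        [{"label": "local", "protocol": "pa_single"},
         {"label": "random", "topology": "random", "protocol": "pa_single"}],
        "Local (Gaussian) vs homogenised random lateral connectivity")
    return exps


EXPERIMENTS = _builtin_experiments()


def run_condition(cond: dict, config: ModelConfig, conn: Connectome | None = None,
                  dynamics_seed: int | None = None,
                  backend: str = "numba") -> dict:
    """Run one condition and summarise waves, rates and silent period."""
    unknown = set(cond) - _CONDITION_KEYS
    if unknown:
        raise ValueError(f"condition has unknown key(s) {sorted(unknown)}")
    cfg = ModelConfig.from_dict(config.to_dict())
    for key in ("tau_ref", "delay_e_mean", "delay_i_mean"):
        if key in cond:
            setattr(cfg.neuron, key, cond[key])
    structural = conn is None or ("delay_e_mean" in cond) or ("delay_i_mean" in cond)
    if structural:
        conn = build_network(cfg)
    if cond.get("topology") == "random":
        conn = randomize_topology(conn, cfg.structure_seed + 1)
    if "variant" in cond:
        conn = build_variant(conn, VARIANTS[cond["variant"]])
    if "inhibition_factor" in cond:
        conn = stimulation.scale_inhibition(conn, cond["inhibition_factor"])
    pulses = stimulation.make_protocol(
        cond.get("protocol", "pa_single"), cfg,
        proportion=cond.get("proportion"),
        interval_ms=cond.get("interval_ms", 2.0))
    record = engine.run(conn, cfg, pulses, dynamics_seed=dynamics_seed,
                        backend=backend)
    onset = cfg.tms.onset_ms
    trace = analysis.smooth(analysis.population_rate(record, "5E"))
    row = {"label": cond.get("label", ""), "dynamics_seed": record.meta["dynamics_seed"]}
    if pulses:
        table = analysis.detect_waves(trace, onset)
        row.update({
            "n_waves": len(table.waves),
            "wave_labels": ",".join(table.labels),
            "wave_times_ms": ";".join(f"{t:.2f}" for t in table.times),
            "wave_amps_hz": ";".join(
                f"{w.amplitude_hz:.1f}" for w in table.waves),
            "isi_mean_ms": float(table.isis.mean()) if table.isis.size else np.nan,
            "d_amp_hz": table.amplitude("D"),
            "i1_amp_hz": table.amplitude("I1"),
            "i2_amp_hz": table.amplitude("I2"),
            "i3_amp_hz": table.amplitude("I3"),
            "i1_time_ms": next((w.time_ms for w in table.waves if w.label == "I1"), np.nan),
            "i2_time_ms": next((w.time_ms for w in table.waves if w.label == "I2"), np.nan),
            "i3_time_ms": next((w.time_ms for w in table.waves if w.label == "I3"), np.nan),
            "silent_period_ms": analysis.silent_period(
                record, _present_excitatory(conn), onset),
            "oscillation": analysis.sustained_oscillation(trace, onset),
        })
    for g in ("2/3E", "5E"):
        if pulses:  # pre-pulse window so the evoked response is excluded
            row[f"rate_{g}_hz"] = analysis.resting_rate(
                record, g, window_ms=min(100.0, onset - cfg.sim.analysis_start),
                t_end_ms=onset)
        else:
            row[f"rate_{g}_hz"] = analysis.resting_rate(record, g, window_ms=200.0)
    row["n_spikes"] = record.n_spikes
    return row


def _present_excitatory(conn: Connectome):
    """Excitatory cortical groups that still receive drive in this connectome."""
    out = []
    for g in analysis.EXCITATORY_CORTICAL_GROUPS:
        idx = conn.group_indices(g)
        if idx.size and conn.background_mask[idx].any():
            out.append(g)
    return out


def run_experiment(name_or_spec, config: ModelConfig | None = None,
                   seeds=(1,), backend: str = "numba") -> pd.DataFrame:
    """Run every condition x dynamics seed of an experiment.

    Structural parameters use the same structure seed throughout, so each
    manipulation is evaluated on the same network instance (sweeps isolate
    the swept parameter).  Returns one summary row per condition x seed.
    """
    spec = EXPERIMENTS[name_or_spec] if isinstance(name_or_spec, str) else name_or_spec
    config = config or ModelConfig()
    base_conn = build_network(config)
    rows = []
    for cond in spec.conditions:
        structural = ("delay_e_mean" in cond) or ("delay_i_mean" in cond)
        conn = None if structural else base_conn
        for seed in seeds:
            row = run_condition(cond, config, conn=conn,
                                dynamics_seed=int(seed), backend=backend)
            row["experiment"] = spec.name
            rows.append(row)
    return pd.DataFrame(rows)
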