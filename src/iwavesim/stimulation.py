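"""TMS modelled as direct current injection into point neurons.

A pulse is a one-step rectangular current delivered at its onset to a random
subset (``proportion``) of the target population: the cortical neurons for
PA-direction stimulation, the premotor group alone for AP-direction
stimulation (the AP pathway enters M1 trans-synaptically through the premotor
projection).  The injected amplitude decays linearly with cortical depth,

    A(z) = A_surface * (1 - (1 - depth_floor) * z / thickness),

so superficial neurons are driven hardest and deep layer-6 neurons may stay
subthreshold.  Stimulus strength is varied through ``proportion``, not
amplitude, matching how intensity is treated in the source experiments.
Paired-pulse protocols are simply two pulses of equal strength separated by
the interstimulus interval.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np

from .config import ModelConfig
from .network import PREMOTOR_GROUP, Connectome

__all__ = [
    "TMSPulse",
    "ProtocolError",
    "paired_pulse",
    "select_targets",
    "depth_scaled_current",
    "scale_inhibition",
    "build_injections",
    "make_protocol",
]


class ProtocolError(ValueError):
    pass


@dataclass(frozen=True)
class TMSPulse:
    """A single TMS pulse.

    ``surface_amplitude_pA``/``depth_floor`` default to the configured values
    when None.  ``direction`` is "PA" (stimulate cortical neurons) or "AP"
    (stimulate the premotor group).
    """

    onset_ms: float
    direction: str = "PA"
    proportion: float = 0.25
    surface_amplitude_pA: float | None = None
    depth_floor: float | None = None

    def __post_init__(self):
        if self.direction not in ("PA", "AP"):
            raise ProtocolError(f"direction must be 'PA' or 'AP', got {self.direction!r}")
        if not (0.0 <= self.proportion <= 1.0):
            raise ProtocolError("stimulated proportion must lie in [0, 1]")


def paired_pulse(first: TMSPulse, interval_ms: float = 2.0) -> list[TMSPulse]:
    """Two pulses of equal strength separated by ``interval_ms``."""
    if interval_ms <= 0:
        raise ProtocolError("paired-pulse interval must be positive")
    return [first, _dc_replace(first, onset_ms=first.onset_ms + interval_ms)]


def select_targets(population: np.ndarray, proportion: float, rng) -> np.ndarray:
    """Uniform random subset of round(proportion * len(population)) neurons."""
    if not (0.0 <= proportion <= 1.0):
        raise ProtocolError("proportion must lie in [0, 1]")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    population = np.asarray(population)
    k = int(round(proportion * len(population)))
    if k == 0:
        return np.empty(0, dtype=np.int64)
    return np.sort(rng.choice(population, size=k, replace=False))


def depth_scaled_current(z_mm, pulse: TMSPulse, config: ModelConfig):
    """Injected current (pA) at depth z: linear decay from the surface value."""
    amp = (pulse.surface_amplitude_pA if pulse.surface_amplitude_pA is not None
           else config.tms.surface_amplitude_pA)
    floor = (pulse.depth_floor if pulse.depth_floor is not None
             else config.tms.depth_floor)
    thick = config.geometry.thickness_mm
    z = np.asarray(z_mm, dtype=float)
    if np.any(z < 0) or np.any(z > thick + 1e-9):
        raise ValueError("depth outside the cortical volume")
    return amp * (1.0 - (1.0 - floor) * z / thick)


def scale_inhibition(conn: Connectome, factor: float) -> Connectome:
    """Multiply every inhibitory synaptic weight by ``factor`` (GABAergic
    efficacy manipulation); excitatory weights untouched."""
    if factor <= 0:
        raise ValueError("inhibition scale factor must be positive")
    weight = conn.weight.copy()
    inhibitory = weight < 0
    weight[inhibitory] *= factor
    from dataclasses import replace
    return replace(conn, weight=weight,
                   background_mask=conn.background_mask.copy(),
                   meta={**conn.meta, "inhibition_factor": factor})


def build_injections(conn: Connectome, config: ModelConfig, pulses,
                     rng) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resolve pulses into (step, neuron, delta_V) injection events.

    The one-step rectangular current of amplitude A deposits charge A*dt,
    i.e. a voltage step A*dt/C_m, at the pulse onset.  Events are sorted by
    step for the kernel's pointer walk.
    """
    sim, p = config.sim, config.neuron
    steps, neurons, dvs = [], [], []
    for pulse in pulses:
        if not (0.0 <= pulse.onset_ms <= sim.duration):
            raise ProtocolError(
                f"pulse onset {pulse.onset_ms} ms outside the simulated window "
                f"[0, {sim.duration}] ms")
        if pulse.direction == "AP":
            if PREMOTOR_GROUP not in conn.group_names:
                raise ProtocolError(
                    "AP stimulation requires a premotor group in the connectome")
            population = conn.group_indices(PREMOTOR_GROUP)
        else:
            population = conn.cortical_indices()
        targets = select_targets(population, pulse.proportion, rng)
        if targets.size == 0:
            continue
        amps = depth_scaled_current(conn.positions[targets, 2], pulse, config)
        step = int(round(pulse.onset_ms / sim.dt))
        steps.append(np.full(targets.size, step, dtype=np.int64))
        neurons.append(targets)
        dvs.append(amps * sim.dt / p.C_m)
    if not steps:
        return (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0))
    step = np.concatenate(steps)
    neuron = np.concatenate(neurons)
    dv = np.concatenate(dvs)
    order = np.argsort(step, kind="stable")
    return step[order], neuron[order], dv[order]


def make_protocol(name: str, config: ModelConfig, proportion: float | None = None,
                  onset_ms: float | None = None, interval_ms: float = 2.0):
    """Named stimulation protocols: pa_single, ap_single, paired, none."""
    onset = config.tms.onset_ms if onset_ms is None else onset_ms
    prop = config.tms.proportion if proportion is None else proportion
    if name == "none":
        return []
    if name == "pa_single":
        return [TMSPulse(onset_ms=onset, direction="PA", proportion=prop)]
    if name == "ap_single":
        return [TMSPulse(onset_ms=onset, direction="AP", proportion=prop)]
    if name == "paired":
        return paired_pulse(
            TMSPulse(onset_ms=onset, direction="PA", proportion=prop), interval_ms)
    raise ProtocolError(f"unknown protocol {name!r}")
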