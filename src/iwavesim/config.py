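"""Model configuration: neuron parameters, group sizes, connectivity tables, geometry.

All defaults are the published parameters of the motor-cortex circuit model:
eight neuron groups (excitatory/inhibitory pairs in layers 2/3, 4, 5, 6) of
38,556 leaky integrate-and-fire neurons placed in a 1 mm^2 x 2.3 mm cortical
volume, group-to-group connection probabilities resolved into explicit synapse
counts via Peters' rule, and distance-dependent (Gaussian) connection sampling.

Every parameter can be overridden from a YAML file; unknown keys are rejected
so typos fail loudly rather than silently falling back to defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "GROUP_NAMES",
    "GROUP_LAYERS",
    "GROUP_SIGNS",
    "FULL_SCALE_COUNTS",
    "CONNECTION_PROBABILITY",
    "ConfigError",
    "NeuronParams",
    "SimParams",
    "ExternalInputParams",
    "Geometry",
    "ConnectivityParams",
    "TMSParams",
    "PremotorParams",
    "ModelConfig",
    "load_config",
    "largest_remainder_counts",
]

# Canonical group order used for every table and array in the package.
GROUP_NAMES: tuple[str, ...] = ("2/3E", "2/3I", "4E", "4I", "5E", "5I", "6E", "6I")
GROUP_LAYERS: dict[str, str] = {
    "2/3E": "2/3", "2/3I": "2/3", "4E": "4", "4I": "4",
    "5E": "5", "5I": "5", "6E": "6", "6I": "6",
}
GROUP_SIGNS: dict[str, str] = {
    g: ("excitatory" if g.endswith("E") else "inhibitory") for g in GROUP_NAMES
}

# Absolute neuron counts of the full-scale model (total 38,556).
FULL_SCALE_COUNTS: dict[str, int] = {
    "2/3E": 10332, "2/3I": 2916, "4E": 2412, "4I": 540,
    "5E": 10944, "5I": 2736, "6E": 7200, "6I": 1476,
}

# Connection probabilities C_a, rows = target group, columns = source group,
# both in GROUP_NAMES order.
CONNECTION_PROBABILITY: np.ndarray = np.array([
    # src: 2/3E    2/3I    4E      4I      5E      5I      6E      6I
    [0.192,  0.3095, 0.3356, 0.5802, 0.0143, 0.0,    0.0159, 0.0],    # -> 2/3E
    [0.252,  0.2553, 0.2558, 0.4183, 0.034,  0.0,    0.008,  0.0],    # -> 2/3I
    [0.016,  0.012,  0.3725, 0.7704, 0.0031, 0.0,    0.0879, 0.0],    # -> 4E
    [0.1334, 0.006,  0.5266, 0.8295, 0.0013, 0.0,    0.2007, 0.0],    # -> 4I
    [0.1902, 0.1202, 0.3785, 0.0592, 0.0377, 0.1662, 0.0396, 0.0],    # -> 5E
    [0.1071, 0.0533, 0.2129, 0.0201, 0.027,  0.1374, 0.0179, 0.0],    # -> 5I
    [0.0318, 0.014,  0.1754, 0.1597, 0.0257, 0.0078, 0.0784, 0.399],  # -> 6E
    [0.0708, 0.002,  0.0269, 0.0101, 0.0125, 0.0031, 0.1276, 0.267],  # -> 6I
])


class ConfigError(ValueError):
    """Raised when a configuration value or file violates the schema."""


def _from_dict(cls, data: dict):
    """Build a dataclass from a dict, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ConfigError(f"{cls.__name__}: expected a mapping, got {type(data).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"{cls.__name__}: unknown key(s) {sorted(unknown)}")
    return cls(**data)


@dataclass
class NeuronParams:
    """Leaky integrate-and-fire neuron and synapse parameters.

    Units: capacitance pF, voltages mV, times ms, currents pA.  A presynaptic
    spike increments the target's synaptic current by ``g*w`` after the
    conduction delay: ``g_e*w`` for excitatory sources, ``g_i*w`` (negative)
    for inhibitory sources.
    """

    C_m: float = 250.0        # membrane capacitance (pF)
    theta: float = -50.0      # spike threshold (mV)
    V_r: float = -65.0        # reset / resting potential (mV)
    tau_ref: float = 2.0      # absolute refractory period (ms)
    tau_m: float = 10.0       # membrane time constant (ms)
    tau_syn: float = 0.5      # synaptic current time constant (ms)
    g_e: float = 1.0          # excitatory weight scale (dimensionless)
    g_i: float = -4.0         # inhibitory weight scale (dimensionless)
    w: float = 87.8           # base synaptic weight (pA)
    delay_e_mean: float = 1.5  # mean excitatory conduction delay (ms)
    delay_i_mean: float = 0.8  # mean inhibitory conduction delay (ms)
    delay_rel_sd: float = 0.5  # delay SD as a fraction of the mean (0 = fixed)

    def validate(self) -> None:
        if self.theta <= self.V_r:
            raise ConfigError("threshold must exceed the reset potential")
        for name in ("C_m", "tau_ref", "tau_m", "tau_syn"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.delay_e_mean <= 0 or self.delay_i_mean <= 0:
            raise ConfigError("mean delays must be positive")
        if self.delay_rel_sd < 0:
            raise ConfigError("delay_rel_sd must be >= 0")


@dataclass
class SimParams:
    dt: float = 0.1                 # integration step (ms)
    duration: float = 250.0         # total simulated time (ms)
    analysis_start: float = 50.0    # transient discarded before analysis (ms)
    init_voltage: str = "uniform"   # "uniform" in [V_r, theta) or "reset"
    integrator: str = "exact"       # "exact" propagator or "euler"

    def validate(self) -> None:
        if self.dt <= 0 or self.duration <= 0:
            raise ConfigError("dt and duration must be positive")
        if self.analysis_start < 0 or self.analysis_start >= self.duration:
            raise ConfigError("analysis_start must lie in [0, duration)")
        if self.init_voltage not in ("uniform", "reset"):
            raise ConfigError("init_voltage must be 'uniform' or 'reset'")
        if self.integrator not in ("exact", "euler"):
            raise ConfigError("integrator must be 'exact' or 'euler'")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


@dataclass
class ExternalInputParams:
    """Poisson background drive from outside the modelled patch.

    Each cortical neuron receives a fixed number of independent 8 Hz fibres
    (2,000 for neurons in excitatory groups, 1,850 for neurons in inhibitory
    groups), aggregated into a single Poisson count per neuron per step.  All
    background fibres are excitatory (weight ``g_e*w``).
    """

    rate_hz: float = 8.0
    k_ext_exc: int = 2000
    k_ext_inh: int = 1850

    def validate(self) -> None:
        if self.rate_hz < 0 or self.k_ext_exc < 0 or self.k_ext_inh < 0:
            raise ConfigError("external input rate and fibre counts must be >= 0")


@dataclass
class Geometry:
    """Cortical patch geometry: 1 mm^2 surface, 2.3 mm deep, four layer bands.

    Layer bands are half-open depth intervals (lo, hi] in mm that tile
    (0, thickness].  The band boundaries are a model choice (only the total
    thickness is constrained); defaults follow human M1 laminar fractions.
    """

    side_mm: float = 1.0
    thickness_mm: float = 2.3
    layer_bounds: dict = field(default_factory=lambda: {
        "2/3": (0.0, 0.9), "4": (0.9, 1.2), "5": (1.2, 1.8), "6": (1.8, 2.3),
    })

    def validate(self) -> None:
        if self.side_mm <= 0 or self.thickness_mm <= 0:
            raise ConfigError("geometry dimensions must be positive")
        order = ("2/3", "4", "5", "6")
        if set(self.layer_bounds) != set(order):
            raise ConfigError("layer_bounds must define layers 2/3, 4, 5, 6")
        prev_hi = 0.0
        for layer in order:
            lo, hi = self.layer_bounds[layer]
            if not (lo < hi):
                raise ConfigError(f"layer {layer}: empty depth interval")
            if abs(lo - prev_hi) > 1e-9:
                raise ConfigError("layer bands must be ordered and tile the thickness")
            prev_hi = hi
        if abs(prev_hi - self.thickness_mm) > 1e-9:
            raise ConfigError("layer bands must end at the full thickness")


@dataclass
class ConnectivityParams:
    """Connection probabilities and spatial radii.

    ``conn_prob[target, source]`` follows GROUP_NAMES order.  Radii (um)
    resolve by connection class: excitatory intralaminar 300 (layer 6: 225),
    excitatory interlaminar (vertical) 50, inhibitory sources always 175.
    """

    conn_prob: list = field(
        default_factory=lambda: CONNECTION_PROBABILITY.tolist())
    radius_lateral_e_um: float = 300.0
    radius_lateral_e_l6_um: float = 225.0
    radius_vertical_e_um: float = 50.0
    radius_inhibitory_um: float = 175.0
    max_multapse_factor: float = 100.0  # cap: K <= factor * N_pre*N_post

    def validate(self) -> None:
        P = np.asarray(self.conn_prob, dtype=float)
        if P.shape != (len(GROUP_NAMES), len(GROUP_NAMES)):
            raise ConfigError("conn_prob must be an 8x8 table in group order")
        if np.any(P < 0) or np.any(P >= 1):
            raise ConfigError("connection probabilities must satisfy 0 <= C_a < 1")
        for name in ("radius_lateral_e_um", "radius_lateral_e_l6_um",
                     "radius_vertical_e_um", "radius_inhibitory_um"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.max_multapse_factor <= 0:
            raise ConfigError("max_multapse_factor must be positive")

    @property
    def prob_matrix(self) -> np.ndarray:
        return np.asarray(self.conn_prob, dtype=float)


@dataclass
class TMSParams:
    """Defaults for a single TMS pulse modelled as a one-step current injection.

    The injected current decays linearly with depth z, reaching
    ``depth_floor`` of the surface value at the bottom of the volume.  The
    pulse amplitude and depth profile are not physiological measurements but
    calibration choices: the surface amplitude must comfortably exceed the
    one-step threshold charge C_m*(theta - V_r)/dt (37,500 pA at default
    parameters) for directly driven neurons to produce a D-wave, and the
    default pair (300,000 pA, floor 0.3) was calibrated so that a default PA
    pulse recruits roughly 60% of layer-5E neurons within 10 ms, the
    activation fraction the modelled experiments report.
    """

    onset_ms: float = 150.0
    proportion: float = 0.25
    surface_amplitude_pA: float = 300000.0
    depth_floor: float = 0.3

    def validate(self) -> None:
        if not (0.0 <= self.proportion <= 1.0):
            raise ConfigError("stimulated proportion must lie in [0, 1]")
        if self.surface_amplitude_pA < 0:
            raise ConfigError("surface amplitude must be >= 0")
        if not (0.0 <= self.depth_floor <= 1.0):
            raise ConfigError("depth_floor must lie in [0, 1]")


@dataclass
class PremotorParams:
    """Premotor afferent population used for AP-direction stimulation.

    The premotor group projects mostly to layer 2/3 with a small fraction to
    layer 5E, with a longer conduction delay than intracortical connections.
    Its size, out-degree, split and delay are model choices (the source
    circuit diagram constrains only the qualitative pattern); all are
    configurable.  Premotor neurons receive no background drive and are only
    activated by AP pulses.
    """

    enabled: bool = True
    n: int = 2000
    synapses_per_neuron: int = 2600
    frac_to_l23: float = 0.9        # remainder targets 5E
    delay_mean_ms: float = 2.0
    delay_rel_sd: float = 0.5

    def validate(self) -> None:
        if self.n < 0 or self.synapses_per_neuron < 0:
            raise ConfigError("premotor sizes must be >= 0")
        if not (0.0 <= self.frac_to_l23 <= 1.0):
            raise ConfigError("frac_to_l23 must lie in [0, 1]")
        if self.frac_to_l23 < 0.5:
            raise ConfigError("the majority of premotor efferents must target layer 2/3")
        if self.delay_mean_ms <= 0:
            raise ConfigError("premotor delay mean must be positive")


@dataclass
class ModelConfig:
    """Complete model description: structure, dynamics, input and stimulation.

    ``scale`` shrinks every group (largest-remainder rounding) while the
    synapse counts are recomputed from the connection probabilities at the
    reduced sizes.  Because per-neuron in-degrees then shrink with scale, a
    reduced model needs a compensation convention:

    * ``"fluctuation"`` (default) — recurrent weights x 1/sqrt(scale),
      preserving the variance of the asynchronous input; the mean deficit is
      restored by a per-neuron DC current computed from ``reference_rates``
      (see :mod:`iwavesim.scaling`), the standard downscaling for studying
      resting-state statistics.
    * ``"linear"`` — recurrent weights x 1/scale, preserving the mean
      recurrent input and the amplitude of synchronous volleys; input
      fluctuations are amplified by 1/sqrt(scale), which inflates
      asynchronous (resting) rates and hyperpolarises the balanced state.
    * ``"none"`` — the tables taken literally at reduced size.

    Background and premotor drive are scale-invariant by construction and are
    never compensated.
    """

    neuron: NeuronParams = field(default_factory=NeuronParams)
    sim: SimParams = field(default_factory=SimParams)
    external: ExternalInputParams = field(default_factory=ExternalInputParams)
    geometry: Geometry = field(default_factory=Geometry)
    connectivity: ConnectivityParams = field(default_factory=ConnectivityParams)
    tms: TMSParams = field(default_factory=TMSParams)
    premotor: PremotorParams = field(default_factory=PremotorParams)
    group_counts: dict = field(default_factory=lambda: dict(FULL_SCALE_COUNTS))
    scale: float = 1.0
    compensation: str = "fluctuation"   # "fluctuation" | "linear" | "none"
    reference_rates: dict | None = None  # group -> Hz, for "fluctuation" mode
    structure_seed: int = 894321
    dynamics_seed: int = 20514

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for part in (self.neuron, self.sim, self.external, self.geometry,
                     self.connectivity, self.tms, self.premotor):
            part.validate()
        if set(self.group_counts) != set(GROUP_NAMES):
            raise ConfigError("group_counts must cover exactly the eight cortical groups")
        for g, n in self.group_counts.items():
            if int(n) != n or n < 1:
                raise ConfigError(f"group {g}: count must be a positive integer")
        if not (0 < self.scale <= 1):
            raise ConfigError("scale must lie in (0, 1]")
        if self.compensation not in ("linear", "fluctuation", "none"):
            raise ConfigError(
                "compensation must be 'linear', 'fluctuation' or 'none'")
        if self.reference_rates is not None:
            bad = set(self.reference_rates) - set(GROUP_NAMES)
            if bad:
                raise ConfigError(f"reference_rates for unknown group(s) {sorted(bad)}")
        # Pulse onsets are validated against the window when a protocol is
        # built, so short diagnostic runs may keep the default TMS block.

    # ------------------------------------------------------------------ io

    @classmethod
    def from_dict(cls, data: dict | None) -> "ModelConfig":
        data = dict(data or {})
        parts = {
            "neuron": NeuronParams, "sim": SimParams,
            "external": ExternalInputParams, "geometry": Geometry,
            "connectivity": ConnectivityParams, "tms": TMSParams,
            "premotor": PremotorParams,
        }
        kwargs = {}
        for key, sub in parts.items():
            if key in data:
                raw = data.pop(key)
                if key == "geometry" and isinstance(raw, dict) and "layer_bounds" in raw:
                    raw = dict(raw)
                    raw["layer_bounds"] = {
                        k: tuple(v) for k, v in raw["layer_bounds"].items()}
                kwargs[key] = _from_dict(sub, raw)
        simple = {"group_counts", "scale", "compensation", "reference_rates",
                  "structure_seed", "dynamics_seed"}
        for key in list(data):
            if key in simple:
                kwargs[key] = data.pop(key)
        if data:
            raise ConfigError(f"ModelConfig: unknown key(s) {sorted(data)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        def convert(obj):
            if dataclasses.is_dataclass(obj):
                return {f.name: convert(getattr(obj, f.name))
                        for f in dataclasses.fields(obj)}
            if isinstance(obj, dict):
                return {k: convert(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [convert(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj
        return convert(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    # --------------------------------------------------------------- scaling

    def scaled(self, scale: float) -> "ModelConfig":
        """Return a copy at reduced ``scale`` with group proportions preserved."""
        if not (0 < scale <= 1):
            raise ConfigError("scale must lie in (0, 1]")
        cfg = ModelConfig.from_dict(self.to_dict())
        full = np.array([FULL_SCALE_COUNTS[g] for g in GROUP_NAMES], dtype=float)
        counts = largest_remainder_counts(full * scale)
        if np.any(counts < 1):
            raise ConfigError(f"scale {scale} produces an empty neuron group")
        cfg.group_counts = {g: int(c) for g, c in zip(GROUP_NAMES, counts)}
        cfg.scale = float(scale)
        cfg.premotor.n = max(1, int(round(self.premotor.n * scale))) \
            if self.premotor.enabled else 0
        cfg.validate()
        return cfg

    @property
    def counts_array(self) -> np.ndarray:
        return np.array([self.group_counts[g] for g in GROUP_NAMES], dtype=np.int64)


def largest_remainder_counts(ideal: np.ndarray) -> np.ndarray:
    """Round non-negative reals to integers preserving the rounded total.

    Floors every entry, then distributes the remaining units to the largest
    fractional remainders (ties broken by index), so group proportions survive
    downscaling without drift in the total.
    """
    ideal = np.asarray(ideal, dtype=float)
    total = int(round(ideal.sum()))
    floors = np.floor(ideal).astype(np.int64)
    short = total - int(floors.sum())
    if short > 0:
        order = np.argsort(-(ideal - floors), kind="stable")
        floors[order[:short]] += 1
    return floors


def load_config(path=None) -> ModelConfig:
    """Load a YAML config; an empty or missing file yields all defaults."""
    if path is None:
        return ModelConfig()
    return ModelConfig.from_yaml(path)
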