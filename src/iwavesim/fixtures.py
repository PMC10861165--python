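"""Reduced-scale network instances for fast tests and desk-scale experiments.

A fixture network preserves the full model's group proportions
(largest-remainder rounding) and recomputes every pairwise synapse count from
the connection probabilities at the reduced group sizes, so the connection
probability semantics — the chance that a given ordered neuron pair is
connected at least once — carry over unchanged.
"""

from __future__ import annotations

from .config import ModelConfig
from .network import Connectome, build_network

__all__ = ["make_fixture_config", "make_fixture_network"]


def make_fixture_config(scale: float, seed: int | None = None,
                        base: ModelConfig | None = None, **overrides) -> ModelConfig:
    cfg = (base or ModelConfig()).scaled(scale)
    if seed is not None:
        cfg.structure_seed = int(seed)
    for key, value in overrides.items():
        if not hasattr(cfg, key):
            raise TypeError(f"unknown config field {key!r}")
        setattr(cfg, key, value)
    cfg.validate()
    return cfg


def make_fixture_network(scale: float, seed: int = 0,
                         base: ModelConfig | None = None) -> Connectome:
    """Build a reduced-scale network (proportions preserved, K recomputed)."""
    cfg = make_fixture_config(scale, seed=seed, base=base)
    return build_network(cfg)
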