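"""Serialization of runs: spike tables, summaries and the run manifest.

Every run directory carries a manifest tying its outputs to the config hash
and the structure/dynamics seeds, so any output file can be regenerated
exactly from configuration alone.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from .engine import SpikeRecord

__all__ = ["RunManifest", "save_spikes", "load_spikes", "save_run"]


@dataclass
class RunManifest:
    config_hash: str
    structure_seed: int | None
    dynamics_seed: int
    code_version: str
    outputs: dict = field(default_factory=dict)
    created_utc: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat())

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def save_spikes(record: SpikeRecord, path: str) -> None:
    record.to_dataframe().to_csv(path, index=False)


def load_spikes(path: str, like: SpikeRecord) -> SpikeRecord:
    """Read a spike table back, reusing group labelling from ``like``."""
    df = pd.read_csv(path)
    return SpikeRecord(
        neuron=df["neuron_id"].to_numpy(np.int64),
        time_ms=df["time_ms"].to_numpy(np.float64),
        group_names=list(like.group_names),
        group_counts=like.group_counts.copy(),
        group_of=like.group_of,
        dt=like.dt, duration_ms=like.duration_ms,
        meta={"loaded_from": str(path)})


def save_run(record: SpikeRecord, out_dir: str, summary: dict | None = None) -> RunManifest:
    """Write spikes (+ optional summary JSON) and the manifest to a directory."""
    from . import __version__
    os.makedirs(out_dir, exist_ok=True)
    outputs = {}
    spike_path = os.path.join(out_dir, "spikes.csv")
    save_spikes(record, spike_path)
    outputs["spikes"] = "spikes.csv"
    neuron_path = os.path.join(out_dir, "neurons.csv")
    pd.DataFrame({
        "id": np.arange(record.n_neurons),
        "group": [record.group_names[g] for g in record.group_of],
    }).to_csv(neuron_path, index=False)
    outputs["neurons"] = "neurons.csv"
    if summary is not None:
        with open(os.path.join(out_dir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
        outputs["summary"] = "summary.json"
    manifest = RunManifest(
        config_hash=record.meta.get("config_hash", ""),
        structure_seed=record.meta.get("structure_seed"),
        dynamics_seed=record.meta.get("dynamics_seed", -1),
        code_version=__version__,
        outputs=outputs)
    manifest.save(os.path.join(out_dir, "manifest.json"))
    return manifest
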