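"""Persistence and run manifests.

Traces go to an HDF5 container with seeds and configuration hashes stored as
attributes; spike times, Ca²⁺ events, response labels and synapse placements
are exported as plain tab-separated text so downstream tools need no special
reader.  A :class:`RunManifest` ties every artifact of a run to the master
seed and config hashes that produced it.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .simulator import TrialRecording

__all__ = [
    "RunManifest",
    "save_recordings",
    "load_recordings",
    "write_spike_table",
    "read_spike_table",
    "write_event_table",
    "write_response_table",
    "config_hash",
]


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunManifest:
    master_seed: int
    config_hashes: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)      # stage -> file path
    version: str = __version__
    started: float = field(default_factory=time.time)

    def add_output(self, stage: str, path) -> None:
        self.outputs[stage] = str(path)

    def write(self, path) -> None:
        payload = {
            "version": self.version,
            "master_seed": self.master_seed,
            "config_hashes": self.config_hashes,
            "outputs": self.outputs,
            "started_unix": self.started,
            "written_unix": time.time(),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        m = cls(d["master_seed"], d["config_hashes"], d["outputs"],
                d["version"], d["started_unix"])
        return m


def save_recordings(path, recordings: list[TrialRecording], attrs: dict | None = None):
    """Write trial recordings to an HDF5 file (one group per trial)."""
    with h5py.File(path, "w") as f:
        for k, v in (attrs or {}).items():
            f.attrs[k] = v
        for i, rec in enumerate(recordings):
            g = f.create_group(f"trial_{i:05d}")
            g.create_dataset("time_ms", data=rec.time, compression="gzip")
            for label, trace in rec.vm_traces.items():
                g.create_dataset(f"vm_{label}", data=trace, compression="gzip")
            g.create_dataset("spike_times_ms", data=rec.somatic_spike_times)
            for k, v in rec.metadata.items():
                if isinstance(v, (int, float, str, bool)):
                    g.attrs[k] = v


def load_recordings(path) -> list[TrialRecording]:
    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f):
            g = f[name]
            traces = {k[3:]: g[k][()] for k in g if k.startswith("vm_")}
            out.append(TrialRecording(g["time_ms"][()], traces,
                                      g["spike_times_ms"][()],
                                      dict(g.attrs)))
    return out


def write_spike_table(path, spikes_by_trial: dict) -> None:
    """Plain text spike export: columns trial_id, spike_ms."""
    rows = [(tid, float(t)) for tid, times in spikes_by_trial.items()
            for t in np.asarray(times)]
    pd.DataFrame(rows, columns=["trial_id", "spike_ms"]).to_csv(
        path, sep="\t", index=False)


def read_spike_table(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    return {tid: g["spike_ms"].to_numpy() for tid, g in df.groupby("trial_id")}


def write_event_table(path, events_by_trial: dict) -> None:
    rows = []
    for tid, events in events_by_trial.items():
        for ev in events:
            rows.append((tid, ev.onset, ev.width, ev.peak, ev.origin))
    pd.DataFrame(rows, columns=["trial_id", "onset_ms", "width_ms",
                                "peak_mv", "origin"]).to_csv(
        path, sep="\t", index=False)


def write_response_table(path, labels_by_trial: dict) -> None:
    rows = [(tid, rc.label, rc.n_aps,
             "" if rc.first_ap_latency is None else rc.first_ap_latency)
            for tid, rc in labels_by_trial.items()]
    pd.DataFrame(rows, columns=["trial_id", "label", "n_aps",
                                "latency_ms"]).to_csv(path, sep="\t", index=False)
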