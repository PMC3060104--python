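"""Configuration, file I/O and test-fixture generation.

Formats are chosen for greppability at small scale and capacity at large
scale: configs are YAML (or JSON -- a YAML subset), spike records are
two-column delimited text (time_ms, neuron_id) with an HDF5 option,
topologies are edge-list CSV, and full-state checkpoints are HDF5.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from banetsim.engine import NetworkState
from banetsim.network import NetworkTopology, build_network
from banetsim.params import (
    LIFParams,
    PlasticityParams,
    StimulusParams,
    TopologyParams,
    dataclass_from_dict,
    default_lif_exc,
    default_lif_inh,
)
from banetsim.rate import RateParams
from banetsim.stimulus import Phase

__all__ = [
    "RunConfig",
    "load_config",
    "dump_config",
    "write_spikes_text",
    "read_spikes_text",
    "write_topology_csv",
    "write_result_h5",
    "save_checkpoint",
    "load_checkpoint",
    "make_fixture",
]


@dataclass
class RunConfig:
    """Top-level run description: model choice plus nested sections."""

    model: str = "snn"  # 'rate' or 'snn'
    seed: int = 0
    n_repeats: int = 1
    out_dir: str = "out"
    topology: TopologyParams = field(default_factory=TopologyParams)
    lif_exc: LIFParams = field(default_factory=default_lif_exc)
    lif_inh: LIFParams = field(default_factory=default_lif_inh)
    stimulus: StimulusParams = field(default_factory=StimulusParams)
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    rate: RateParams = field(default_factory=RateParams)
    phases: list[Phase] = field(default_factory=list)

    def validate(self) -> None:
        if self.model not in ("rate", "snn"):
            raise ValueError("model must be 'rate' or 'snn'")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be at least 1")
        for section in (self.topology, self.lif_exc, self.lif_inh, self.stimulus,
                        self.plasticity, self.rate):
            section.validate()
        for phase in self.phases:
            phase.validate()


_SECTION_TYPES = {
    "topology": TopologyParams,
    "lif_exc": LIFParams,
    "lif_inh": LIFParams,
    "stimulus": StimulusParams,
    "plasticity": PlasticityParams,
    "rate": RateParams,
}


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON config; unknown keys are rejected and
    defaults fill any omitted section or field."""
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    known_top = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known_top
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key in _SECTION_TYPES:
            if not isinstance(value, dict):
                raise ValueError(f"section {key!r} must be a mapping")
            if key == "lif_exc":
                base = dataclasses.asdict(default_lif_exc())
            elif key == "lif_inh":
                base = dataclasses.asdict(default_lif_inh())
            else:
                base = {}
            base.update(value)
            if "threshold_bimodal_mV" in base:
                base["threshold_bimodal_mV"] = tuple(base["threshold_bimodal_mV"])
            kwargs[key] = dataclass_from_dict(_SECTION_TYPES[key], base)
        elif key == "phases":
            kwargs[key] = [dataclass_from_dict(Phase, p) for p in value]
        else:
            kwargs[key] = value
    cfg = RunConfig(**kwargs)
    cfg.validate()
    return cfg


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    data = dataclasses.asdict(cfg)
    data["lif_exc"]["threshold_bimodal_mV"] = list(data["lif_exc"]["threshold_bimodal_mV"])
    data["lif_inh"]["threshold_bimodal_mV"] = list(data["lif_inh"]["threshold_bimodal_mV"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def write_spikes_text(path: str | Path, times_ms: np.ndarray, ids: np.ndarray) -> None:
    """Two-column delimited spike record: time_ms <TAB> neuron_id."""
    arr = np.column_stack([np.asarray(times_ms, dtype=float), np.asarray(ids, dtype=float)])
    np.savetxt(path, arr, fmt=["%.3f", "%d"], delimiter="\t", header="time_ms\tneuron_id")


def read_spikes_text(path: str | Path):
    arr = np.loadtxt(path, ndmin=2)
    if arr.size == 0:
        return np.empty(0), np.empty(0, dtype=np.int64)
    return arr[:, 0], arr[:, 1].astype(np.int64)


def write_topology_csv(path: str | Path, net: NetworkTopology) -> None:
    net.to_frame().to_csv(path, index=False)


def write_result_h5(path: str | Path, phases) -> None:
    """Spike records, weight logs and Vm traces per phase, HDF5 groups."""
    with h5py.File(path, "w") as fh:
        for p in phases:
            grp = fh.create_group(p.name)
            grp.attrs["t0_ms"] = p.t0_ms
            grp.attrs["duration_ms"] = p.duration_ms
            grp.attrs["context_index"] = p.context_index
            grp.create_dataset("spike_times_ms", data=p.spike_times_ms)
            grp.create_dataset("spike_ids", data=p.spike_ids)
            grp.create_dataset("cs_onsets_ms", data=p.cs_onsets_ms)
            grp.create_dataset("probe_times_ms", data=p.probe_times_ms)
            grp.create_dataset("w_cs_log", data=p.w_cs_log)
            grp.create_dataset("w_ctx_log", data=p.w_ctx_log)
            if p.vm_mV.size:
                grp.create_dataset("vm_mV", data=p.vm_mV)
                grp.create_dataset("gE_nS", data=p.gE_nS)
                grp.create_dataset("gI_nS", data=p.gI_nS)
                grp.create_dataset("vm_ids", data=p.vm_ids)
            if p.free_vm_mV.size:
                grp.create_dataset("free_vm_mV", data=p.free_vm_mV)
                grp.create_dataset("free_ids", data=p.free_ids)


_STATE_FIELDS = ("V", "gE", "gI", "refr", "buf", "c", "h", "w_cs", "w_ctx")


def save_checkpoint(path: str | Path, state: NetworkState) -> None:
    """Serialise the full dynamical state (membranes, conductances, in-flight
    spikes, tags, weights) so later phases can resume exactly."""
    with h5py.File(path, "w") as fh:
        for name in _STATE_FIELDS:
            fh.create_dataset(name, data=getattr(state, name))
        fh.attrs["t_ms"] = state.t_ms


def load_checkpoint(path: str | Path) -> NetworkState:
    with h5py.File(path, "r") as fh:
        kwargs = {name: fh[name][...] for name in _STATE_FIELDS}
        kwargs["refr"] = kwargs["refr"].astype(np.int32)
        return NetworkState(t_ms=float(fh.attrs["t_ms"]), **kwargs)


def make_fixture(kind: str, seed: int = 0, out_dir: str | Path | None = None):
    """Deterministic miniature fixtures for tests and demos.

    * ``tiny_network``   -- 20 EXC + 4 INH fully specified topology.
    * ``canned_spikes``  -- dict of spike records with known statistics:
      'sync' (perfectly coincident volleys), 'poisson' (independent 10 Hz
      trains), 'empty'.
    * ``binary_recruitment`` -- all-or-none per-trial response matrix whose
      neurons switch on at known trials {1, 3, 5} (0-based).
    """
    if kind == "tiny_network":
        params = TopologyParams(
            n_exc=20, n_inh=4, p_ee=0.2, p_ei=0.5, p_ie=0.5, p_ii=0.5,
        )
        net = build_network(params, seed=seed)
        if out_dir is not None:
            write_topology_csv(Path(out_dir) / "tiny_network.csv", net)
        return net
    if kind == "canned_spikes":
        rng = np.random.default_rng(seed)
        n, dur = 20, 10_000.0
        volleys = np.arange(50.0, dur, 100.0)
        sync_times = np.repeat(volleys, n)
        sync_ids = np.tile(np.arange(n), len(volleys))
        order = np.argsort(sync_times, kind="stable")
        poisson_times, poisson_ids = [], []
        for i in range(n):
            k = rng.poisson(10.0 * dur * 1e-3)
            poisson_times.append(np.sort(rng.uniform(0, dur, k)))
            poisson_ids.append(np.full(k, i))
        pt = np.concatenate(poisson_times)
        pi = np.concatenate(poisson_ids).astype(np.int64)
        po = np.argsort(pt, kind="stable")
        out = {
            "sync": (sync_times[order], sync_ids[order], dur),
            "poisson": (pt[po], pi[po], dur),
            "empty": (np.empty(0), np.empty(0, dtype=np.int64), dur),
        }
        if out_dir is not None:
            for name, (t, i, _) in out.items():
                write_spikes_text(Path(out_dir) / f"spikes_{name}.txt", t, i)
        return out
    if kind == "binary_recruitment":
        n_trials = 8
        switch = {0: 1, 1: 3, 2: 5}
        counts = np.zeros((3, n_trials), dtype=np.int64)
        for neuron, trial in switch.items():
            counts[neuron, trial:] = 2
        if out_dir is not None:
            pd.DataFrame(counts).to_csv(Path(out_dir) / "binary_recruitment.csv", index=False)
        return counts, switch
    raise ValueError(f"unknown fixture kind {kind!r}")
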