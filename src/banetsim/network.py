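"""Random recurrent BA network construction.

The topology is stored in compressed sparse row (CSR) form keyed by the
presynaptic neuron, which is what the clock-driven simulation loop consumes
to deliver delayed spikes.  Neuron ids 0..n_exc-1 are excitatory,
n_exc..n_exc+n_inh-1 inhibitory; the synaptic sign is applied by presynaptic
class at delivery time, so stored weights are non-negative conductance
increments (nS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from banetsim.params import TopologyParams

__all__ = ["NetworkTopology", "build_network"]


@dataclass
class NetworkTopology:
    params: TopologyParams
    indptr: np.ndarray  # (n_total + 1,) int64, CSR row pointers by source
    targets: np.ndarray  # (n_edges,) int32
    weights_nS: np.ndarray  # (n_edges,) float64, >= 0
    delays_ms: np.ndarray  # (n_edges,) float64
    delay_steps: np.ndarray  # (n_edges,) int32, delay rounded to the dt grid
    dt_ms: float
    seed: int

    @property
    def n_exc(self) -> int:
        return self.params.n_exc

    @property
    def n_inh(self) -> int:
        return self.params.n_inh

    @property
    def n_total(self) -> int:
        return self.params.n_total

    @property
    def n_edges(self) -> int:
        return int(self.targets.size)

    def out_edges(self, source: int) -> slice:
        return slice(int(self.indptr[source]), int(self.indptr[source + 1]))

    def in_degrees(self) -> pd.DataFrame:
        """Per-neuron in-degree split by presynaptic class."""
        n = self.n_total
        deg_e = np.zeros(n, dtype=int)
        deg_i = np.zeros(n, dtype=int)
        for src in range(n):
            sl = self.out_edges(src)
            tgt = self.targets[sl]
            if src < self.n_exc:
                np.add.at(deg_e, tgt, 1)
            else:
                np.add.at(deg_i, tgt, 1)
        return pd.DataFrame({"in_from_exc": deg_e, "in_from_inh": deg_i})

    def to_frame(self) -> pd.DataFrame:
        """Edge list as a tidy frame (source, target, weight_nS, delay_ms, class)."""
        n_edges = self.n_edges
        sources = np.repeat(np.arange(self.n_total), np.diff(self.indptr))
        cls = np.where(sources < self.n_exc, "E", "I")
        return pd.DataFrame(
            {
                "source": sources.astype(np.int32),
                "target": self.targets,
                "weight_nS": self.weights_nS,
                "delay_ms": self.delays_ms,
                "class": cls,
            }
        )


def _round_delay_steps(delays_ms: np.ndarray, dt_ms: float) -> np.ndarray:
    """Round delays to the integration grid: nearest step, minimum one step.

    Sub-dt delays (e.g. the 0.2-1 ms sweep at dt = 0.1 ms) therefore require
    a dt no coarser than the smallest delay of interest.
    """
    steps = np.rint(delays_ms / dt_ms).astype(np.int32)
    return np.maximum(steps, 1)


def build_network(params: TopologyParams, seed: int, dt_ms: float = 0.1) -> NetworkTopology:
    """Draw a random recurrent network (independent Bernoulli connections).

    Reproducible for a fixed (params, seed, dt).  Self-connections are
    permitted.  Per-edge delays are i.i.d. uniform on the configured range and
    rounded onto the dt grid for the simulation loop.
    """
    params.validate()
    if dt_ms <= 0:
        raise ValueError("dt_ms must be positive")
    rng = np.random.default_rng(seed)
    n_exc, n_inh, n = params.n_exc, params.n_inh, params.n_total

    indptr = np.zeros(n + 1, dtype=np.int64)
    tgt_chunks: list[np.ndarray] = []
    w_chunks: list[np.ndarray] = []
    for src in range(n):
        if src < n_exc:
            p_to_e, p_to_i = params.p_ee, params.p_ei
            w_to_e, w_to_i = params.w_ee_nS, params.w_ei_nS
        else:
            p_to_e, p_to_i = params.p_ie, params.p_ii
            w_to_e, w_to_i = params.w_ie_nS, params.w_ii_nS
        te = np.flatnonzero(rng.random(n_exc) < p_to_e).astype(np.int32)
        ti = (np.flatnonzero(rng.random(n_inh) < p_to_i) + n_exc).astype(np.int32)
        tgt_chunks.append(te)
        tgt_chunks.append(ti)
        w_chunks.append(np.full(te.size, w_to_e))
        w_chunks.append(np.full(ti.size, w_to_i))
        indptr[src + 1] = indptr[src] + te.size + ti.size

    targets = np.concatenate(tgt_chunks) if tgt_chunks else np.empty(0, dtype=np.int32)
    weights = np.concatenate(w_chunks) if w_chunks else np.empty(0)
    delays = rng.uniform(params.delay_min_ms, params.delay_max_ms, size=targets.size)
    return NetworkTopology(
        params=params,
        indptr=indptr,
        targets=targets,
        weights_nS=weights,
        delays_ms=delays,
        delay_steps=_round_delay_steps(delays, dt_ms),
        dt_ms=dt_ms,
        seed=seed,
    )
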