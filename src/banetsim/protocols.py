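"""Scripted end-to-end experiments on the spiking BA network.

Every experiment is described by an :class:`ExperimentSpec` (network +
stimulus + plasticity parameters, a phase schedule, a master seed) and
executed by :class:`ExperimentRunner`, which owns the network, the per-neuron
thresholds, the context assignment and the full dynamical state, and runs the
phases in order, carrying state (and plastic weights) across phase
boundaries.  Eligibility tags are reset between phases; weights persist.

The standard protocol is two pre-conditioning CS probes in context A
(readout, plasticity off), five CS-US presentations in context A
(conditioning) and six CS presentations in context B (extinction).  Renewal,
over-training, inhibition blockade, context removal and parameter sweeps are
variations layered on top.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from banetsim import analysis
from banetsim.engine import (
    NetworkState,
    NeuronArrays,
    PhaseResult,
    init_state,
    make_neuron_arrays,
    simulate_phase,
)
from banetsim.network import NetworkTopology, build_network
from banetsim.params import (
    LIFParams,
    PlasticityParams,
    StimulusParams,
    TopologyParams,
    default_lif_exc,
    default_lif_inh,
    derive_seed,
    scaled_topology,
)
from banetsim.stimulus import (
    CONTEXT_LABELS,
    ContextAssignment,
    Phase,
    assign_contexts,
    compile_program,
)

logger = logging.getLogger("banetsim")

__all__ = [
    "ExperimentSpec",
    "ExperimentResult",
    "ExperimentRunner",
    "default_spec",
    "baseline_spec",
    "run_conditioning_extinction",
    "run_renewal",
    "run_overtraining",
    "run_blockade",
    "run_context_removal",
    "run_sweep",
    "run_repeats",
]


@dataclass
class ExperimentSpec:
    topology: TopologyParams = field(default_factory=TopologyParams)
    lif_exc: LIFParams = field(default_factory=default_lif_exc)
    lif_inh: LIFParams = field(default_factory=default_lif_inh)
    stimulus: StimulusParams = field(default_factory=StimulusParams)
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    phases: list[Phase] = field(default_factory=list)
    seed: int = 0
    n_repeats: int = 1
    dt_ms: float = 0.1
    n_free_vm: int = 0  # free-Vm shadows recorded per context group

    def validate(self) -> None:
        self.topology.validate()
        self.lif_exc.validate()
        self.lif_inh.validate()
        self.stimulus.validate()
        self.plasticity.validate()
        for phase in self.phases:
            phase.validate()
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be at least 1")
        if self.dt_ms <= 0:
            raise ValueError("dt must be positive")


def default_spec(
    seed: int = 0,
    scale: float = 1.0,
    overlap: float = 0.0,
    n_cond: int = 5,
    n_ext: int = 6,
    pre_trials: int = 2,
    n_free_vm: int = 0,
    ext_neuromod: float = 0.4,
    **overrides,
) -> ExperimentSpec:
    """Standard conditioning -> extinction experiment.

    ``scale`` shrinks the network while preserving in-degrees (see
    :func:`banetsim.params.scaled_topology`); ``overlap`` sets the fraction of
    shared context targets between contexts A and B.
    """
    topo = scaled_topology(TopologyParams(), scale) if scale != 1.0 else TopologyParams()
    stim = StimulusParams(overlap_fraction=overlap)
    phases = []
    if pre_trials:
        phases.append(Phase("pre", "A", pre_trials, plastic=False))
    phases.append(Phase("conditioning", "A", n_cond, plastic=True))
    phases.append(Phase("extinction", "B", n_ext, plastic=True, neuromod_gain=ext_neuromod))
    spec = ExperimentSpec(
        topology=topo, stimulus=stim, phases=phases, seed=seed, n_free_vm=n_free_vm, **overrides
    )
    spec.validate()
    return spec


def baseline_spec(seed: int = 0, duration_ms: float = 11000.0, scale: float = 1.0, **overrides) -> ExperimentSpec:
    """Background drive only: no CS, no context input."""
    topo = scaled_topology(TopologyParams(), scale) if scale != 1.0 else TopologyParams()
    spec = ExperimentSpec(
        topology=topo,
        phases=[Phase("baseline", None, 0, plastic=False, duration_ms=duration_ms)],
        seed=seed,
        **overrides,
    )
    spec.validate()
    return spec


@dataclass
class ExperimentResult:
    spec: ExperimentSpec
    repeat: int
    assignment: ContextAssignment
    phases: list[PhaseResult]
    extra: dict = field(default_factory=dict)  # named extra phases (renewal variants)

    def phase(self, name: str) -> PhaseResult:
        for p in self.phases:
            if p.name == name:
                return p
        if name in self.extra:
            return self.extra[name]
        raise KeyError(f"no phase named {name!r}")

    @property
    def n_exc(self) -> int:
        return self.spec.topology.n_exc

    @property
    def n_inh(self) -> int:
        return self.spec.topology.n_inh

    def spikes_frame(self) -> pd.DataFrame:
        frames = []
        for p in self.phases:
            frames.append(
                pd.DataFrame(
                    {"time_ms": p.spike_times_ms, "neuron_id": p.spike_ids, "phase": p.name}
                )
            )
        return pd.concat(frames, ignore_index=True)

    def evoked_counts(self, phase_name: str, window_ms: float = 60.0) -> np.ndarray:
        """(n_total, n_trials) spike counts in the post-onset response window."""
        p = self.phase(phase_name)
        return analysis.evoked_response(
            p.spike_times_ms,
            p.spike_ids,
            self.spec.topology.n_total,
            p.cs_onsets_ms,
            window_ms,
        )

    def classify(self, cond_phase: str = "conditioning", ext_phase: str = "extinction", **kwargs):
        cond = self.evoked_counts(cond_phase, kwargs.pop("window_ms", 60.0))[: self.n_exc]
        ext = self.evoked_counts(ext_phase, 60.0)[: self.n_exc]
        return analysis.classify_neurons(cond, ext, **kwargs)

    def weight_frame(self) -> pd.DataFrame:
        """Mean plastic weights per synapse class at every CS offset.

        Classes: CS afferents onto the context-A set and the context-B set,
        and the CTX_A / CTX_B afferents onto their own sets.
        """
        mem = self.assignment.members
        set_a = mem.get("A", np.empty(0, dtype=int))
        set_b = mem.get("B", np.empty(0, dtype=int))
        rows = []
        for p in self.phases + list(self.extra.values()):
            times = np.concatenate([[p.t0_ms], p.probe_times_ms])
            for row_i, t in enumerate(times):
                rows.append((p.name, t, "CS->A-set", p.w_cs_log[row_i, set_a].mean() if len(set_a) else np.nan))
                rows.append((p.name, t, "CS->B-set", p.w_cs_log[row_i, set_b].mean() if len(set_b) else np.nan))
                rows.append((p.name, t, "CTX_A", p.w_ctx_log[row_i, set_a, 0].mean() if len(set_a) else np.nan))
                rows.append((p.name, t, "CTX_B", p.w_ctx_log[row_i, set_b, 1].mean() if len(set_b) else np.nan))
        return pd.DataFrame(rows, columns=["phase", "time_ms", "synapse_class", "mean_w_nS"])

    def population_rates(self, phase_name: str, subset: np.ndarray) -> float:
        """Mean rate (Hz) of ``subset`` over the whole named phase."""
        p = self.phase(phase_name)
        n_spk = np.isin(p.spike_ids, subset).sum()
        return n_spk / (len(subset) * p.duration_ms * 1e-3)


class ExperimentRunner:
    """Builds a network realisation and runs phases, carrying state."""

    def __init__(self, spec: ExperimentSpec, repeat: int = 0):
        spec.validate()
        self.spec = spec
        self.repeat = repeat
        master = derive_seed(spec.seed, "repeat", repeat)
        self.master = master
        self.net: NetworkTopology = build_network(
            spec.topology, derive_seed(master, "network"), spec.dt_ms
        )
        rng_thr = np.random.default_rng(derive_seed(master, "thresholds"))
        self.neurons: NeuronArrays = make_neuron_arrays(
            spec.lif_exc, spec.lif_inh, spec.topology.n_exc, spec.topology.n_inh, spec.dt_ms, rng_thr
        )
        self.assignment = assign_contexts(
            spec.topology.n_exc,
            spec.stimulus.ctx_fraction,
            spec.stimulus.overlap_fraction,
            spec.stimulus.n_contexts,
            derive_seed(master, "contexts"),
        )
        self.ctx_member = self.assignment.membership_matrix(spec.stimulus.n_contexts)
        max_delay = int(self.net.delay_steps.max()) if self.net.n_edges else 1
        self.state: NetworkState = init_state(
            self.neurons, spec.plasticity, spec.stimulus.n_contexts, max_delay
        )
        self._free_ids = self._pick_free_ids()
        self.phase_index = 0
        self.results: list[PhaseResult] = []

    def _pick_free_ids(self) -> np.ndarray:
        n = self.spec.n_free_vm
        if not n:
            return np.empty(0, dtype=np.int64)
        rng = np.random.default_rng(derive_seed(self.master, "free_vm"))
        ids = []
        for label in ("A", "B"):
            members = self.assignment.members.get(label)
            if members is not None and len(members):
                ids.append(rng.choice(members, size=min(n, len(members)), replace=False))
        return np.sort(np.concatenate(ids)) if ids else np.empty(0, dtype=np.int64)

    def run_phase(self, phase: Phase) -> PhaseResult:
        spec = self.spec
        sched = compile_program([phase], spec.stimulus)[0]
        inactive = None
        if phase.inactive_inh_fraction > 0:
            rng = np.random.default_rng(derive_seed(self.master, "blockade", self.phase_index))
            n_off = int(round(phase.inactive_inh_fraction * spec.topology.n_inh))
            inactive = spec.topology.n_exc + rng.choice(
                spec.topology.n_inh, size=n_off, replace=False
            )
        result = simulate_phase(
            self.net,
            self.neurons,
            spec.stimulus,
            spec.plasticity,
            sched,
            self.ctx_member,
            self.state,
            seed=derive_seed(self.master, "phase", self.phase_index),
            dt_ms=spec.dt_ms,
            free_ids=self._free_ids,
            inactive_inh_ids=inactive,
        )
        self.state.reset_traces()
        self.phase_index += 1
        self.results.append(result)
        logger.info(
            "phase %s done: %.0f ms, %d trials, %d spikes",
            result.name, result.duration_ms, len(result.cs_onsets_ms),
            result.spike_times_ms.size,
        )
        return result

    def run(self) -> ExperimentResult:
        for phase in self.spec.phases:
            self.run_phase(phase)
        return ExperimentResult(
            spec=self.spec, repeat=self.repeat, assignment=self.assignment, phases=self.results
        )

    def snapshot(self) -> tuple[NetworkState, int]:
        """Checkpoint of the dynamical state and phase counter."""
        return self.state.copy(), self.phase_index

    def restore(self, snapshot: tuple[NetworkState, int]) -> None:
        state, idx = snapshot
        self.state = state.copy()
        self.phase_index = idx


def run_conditioning_extinction(spec: ExperimentSpec, repeat: int = 0) -> ExperimentResult:
    """Full pipeline: build, stimulate, plastic updates at CS offsets, record."""
    return ExperimentRunner(spec, repeat).run()


def _renewal_phase(context: str, n_trials: int) -> Phase:
    # Renewal presentations are readouts: plasticity probes disabled, so the
    # weight log demonstrates that the activity switch is purely a network
    # effect (no weight change during the renewal block).
    return Phase("renewal_" + context, context, n_trials, plastic=False)


def run_renewal(
    spec: ExperimentSpec,
    renewal_context: str = "A",
    n_renewal_trials: int = 3,
    repeat: int = 0,
) -> ExperimentResult:
    """Conditioning + extinction followed by CS presentations in a new context.

    ``renewal_context='A'`` is ABA renewal (original conditioning context),
    ``'C'`` is ABC renewal (novel context).
    """
    if renewal_context not in CONTEXT_LABELS:
        raise ValueError(f"unknown renewal context {renewal_context!r}")
    runner = ExperimentRunner(spec, repeat)
    for phase in spec.phases:
        runner.run_phase(phase)
    renewal = runner.run_phase(_renewal_phase(renewal_context, n_renewal_trials))
    result = ExperimentResult(
        spec=spec, repeat=repeat, assignment=runner.assignment, phases=runner.results
    )
    result.extra["renewal"] = renewal
    return result


def run_overtraining(
    spec: ExperimentSpec,
    extra_extinction_trials: int = 12,
    n_renewal_trials: int = 3,
    repeat: int = 0,
) -> ExperimentResult:
    """Massed extinction, then renewal probed in both ABA and ABC variants.

    The run branches from a checkpoint at the end of (over-trained)
    extinction, so both renewal variants share the identical learning history.
    """
    if extra_extinction_trials < 0:
        raise ValueError("extra trials must be non-negative")
    phases = [
        replace(p, n_trials=p.n_trials + extra_extinction_trials) if p.name == "extinction" else p
        for p in spec.phases
    ]
    spec_ot = replace(spec, phases=phases)
    runner = ExperimentRunner(spec_ot, repeat)
    for phase in spec_ot.phases:
        runner.run_phase(phase)
    snap = runner.snapshot()
    result = ExperimentResult(
        spec=spec_ot, repeat=repeat, assignment=runner.assignment, phases=list(runner.results)
    )
    for ctx in ("A", "C"):
        runner.restore(snap)
        res = runner.run_phase(_renewal_phase(ctx, n_renewal_trials))
        result.extra["renewal_" + ctx] = res
    return result


def run_blockade(
    spec: ExperimentSpec, inactive_inh_fraction: float, repeat: int = 0
) -> ExperimentResult:
    """Silence a fraction of inhibitory neurons during extinction acquisition."""
    if not 0.0 <= inactive_inh_fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    phases = [
        replace(p, inactive_inh_fraction=inactive_inh_fraction) if p.name == "extinction" else p
        for p in spec.phases
    ]
    return ExperimentRunner(replace(spec, phases=phases), repeat).run()


def run_context_removal(
    spec: ExperimentSpec, removal_point: str, n_test_trials: int = 3, repeat: int = 0
) -> ExperimentResult:
    """Zero all contextual input from the removal point onwards.

    ``after_conditioning``: extinction training proceeds without any context
    input.  ``after_extinction``: the normal protocol runs, followed by CS
    test presentations with context input removed.
    """
    if removal_point == "after_conditioning":
        phases = [replace(p, context=None) if p.name == "extinction" else p for p in spec.phases]
        return ExperimentRunner(replace(spec, phases=phases), repeat).run()
    if removal_point == "after_extinction":
        phases = spec.phases + [Phase("no_ctx_test", None, n_test_trials, plastic=False)]
        return ExperimentRunner(replace(spec, phases=phases), repeat).run()
    raise ValueError("removal_point must be 'after_conditioning' or 'after_extinction'")


def run_repeats(spec: ExperimentSpec, runner=run_conditioning_extinction, **kwargs) -> list[ExperimentResult]:
    """Run ``spec.n_repeats`` independent realisations (derived seeds)."""
    return [runner(spec, repeat=rep, **kwargs) for rep in range(spec.n_repeats)]


def _ongoing_spec(base: ExperimentSpec, topology: TopologyParams, duration_ms: float) -> ExperimentSpec:
    return replace(
        base,
        topology=topology,
        phases=[Phase("ongoing", None, 0, plastic=False, duration_ms=duration_ms)],
    )


def run_sweep(
    spec: ExperimentSpec,
    axis: str,
    values,
    reduced_repeats: int = 1,
    duration_ms: float = 3000.0,
    synchrony_bin_ms: float = 2.0,
) -> pd.DataFrame:
    """Parameter sweeps: context overlap, inhibitory connectivity, delays,
    synaptic strength.

    ``ctx_overlap`` runs the full conditioning+extinction protocol per value
    and reports classification counts and the distinct-population criterion;
    the other axes run ongoing-activity simulations and report the synchrony
    index and spectral peak of the inhibitory population.
    """
    rows = []
    for value in values:
        for rep in range(reduced_repeats):
            if axis == "ctx_overlap":
                spec_v = replace(spec, stimulus=replace(spec.stimulus, overlap_fraction=float(value)))
                res = run_conditioning_extinction(spec_v, repeat=rep)
                cls = res.classify()
                ext_counts = res.evoked_counts("extinction")[: res.n_exc]
                distinct = analysis.distinct_populations(cls.labels, ext_counts)
                rows.append(
                    {
                        "axis": axis,
                        "value": float(value),
                        "repeat": rep,
                        "n_fear": int((cls.labels == "fear").sum()),
                        "n_extinction": int((cls.labels == "extinction").sum()),
                        "n_persistent": int((cls.labels == "persistent").sum()),
                        "distinct": bool(distinct),
                    }
                )
                continue
            if axis == "inh_connectivity":
                topo = replace(spec.topology, p_ii=float(value))
            elif axis == "syn_strength":
                topo = replace(spec.topology, w_ii_nS=float(value), w_ie_nS=float(value))
            elif axis == "delay_range":
                lo, hi = value
                topo = replace(spec.topology, delay_min_ms=float(lo), delay_max_ms=float(hi))
            else:
                raise ValueError(f"unknown sweep axis {axis!r}")
            spec_v = _ongoing_spec(spec, topo, duration_ms)
            res = run_conditioning_extinction(spec_v, repeat=rep)
            p = res.phases[0]
            inh_ids = np.arange(spec_v.topology.n_exc, spec_v.topology.n_total)
            sync = analysis.synchrony_and_spectrum(
                p.spike_times_ms,
                p.spike_ids,
                inh_ids,
                t0_ms=500.0,
                t1_ms=p.duration_ms,
                bin_ms=synchrony_bin_ms,
            )
            inh_rate = np.isin(p.spike_ids, inh_ids).sum() / (len(inh_ids) * p.duration_ms * 1e-3)
            rows.append(
                {
                    "axis": axis,
                    "value": value if axis != "delay_range" else f"{value[0]}-{value[1]}",
                    "repeat": rep,
                    "synchrony_index": sync.synchrony_index,
                    "peak_frequency_Hz": sync.peak_frequency_Hz,
                    "inh_rate_Hz": inh_rate,
                }
            )
    return pd.DataFrame(rows)
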