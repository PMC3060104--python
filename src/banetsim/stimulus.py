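"""External input streams and experiment phase schedules.

Three stream classes drive the spiking network, all as independent
homogeneous Poisson processes (one private generator per target neuron per
stream, so correlations between neurons arise only through recurrence):

* **CS** -- 50 ms pulses delivered to every neuron.  A single stream plays
  both the US and CS roles.
* **CTX** -- tonic context-specific drive to fixed subsets of excitatory
  neurons (default 20% per context, optionally overlapping).
* **BKG** -- nonspecific tonic background to all neurons.

During simulation the engine draws the Poisson counts on the fly from the
phase seed; :func:`compile_program` turns a phase list into the deterministic
schedule (CS windows, active context, durations) the engine consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from banetsim.params import StimulusParams, derive_seed

__all__ = [
    "Phase",
    "ContextAssignment",
    "PhaseSchedule",
    "make_poisson_stream",
    "assign_contexts",
    "compile_program",
    "program_frame",
]

#: context labels in canonical order; label -> index used by the engine
CONTEXT_LABELS = ("A", "B", "C")


@dataclass
class Phase:
    """One phase of an experiment: a context, a number of CS trials, flags.

    ``context=None`` removes contextual input entirely (context-removal
    protocols).  ``plastic=False`` marks readout presentations whose CS
    offsets are not probed by the plasticity rule (pre-conditioning tests and
    renewal).  ``inactive_inh_fraction`` silences that fraction of inhibitory
    neurons for the duration of the phase (blockade experiments).
    """

    name: str
    context: str | None
    n_trials: int
    plastic: bool = True
    inactive_inh_fraction: float = 0.0
    duration_ms: float | None = None  # override; default warmup + n_trials * ITI
    warmup_ms: float = 1000.0
    #: phase-level neuromodulator level multiplying the potentiation step; the
    #: US present during conditioning releases more neuromodulator than the
    #: CS-alone extinction trials, biasing learning towards conditioning.
    neuromod_gain: float = 1.0

    def validate(self) -> None:
        if self.context is not None and self.context not in CONTEXT_LABELS:
            raise ValueError(f"unknown context label {self.context!r}")
        if self.n_trials < 0:
            raise ValueError("n_trials must be non-negative")
        if not 0.0 <= self.inactive_inh_fraction <= 1.0:
            raise ValueError("inactive_inh_fraction must lie in [0, 1]")
        if self.neuromod_gain < 0:
            raise ValueError("neuromod_gain must be non-negative")


@dataclass
class ContextAssignment:
    """Fixed per-context target sets of excitatory neuron ids."""

    members: dict[str, np.ndarray]
    overlap: np.ndarray  # ids shared between contexts A and B
    n_exc: int

    def membership_matrix(self, n_contexts: int) -> np.ndarray:
        """(n_contexts, n_exc) uint8 membership, row order = CONTEXT_LABELS."""
        mat = np.zeros((n_contexts, self.n_exc), dtype=np.uint8)
        for k, label in enumerate(CONTEXT_LABELS[:n_contexts]):
            if label in self.members:
                mat[k, self.members[label]] = 1
        return mat


def make_poisson_stream(rate_Hz: float, t0_ms: float, t1_ms: float, seed: int) -> np.ndarray:
    """Event times (ms) of a homogeneous Poisson process on [t0, t1)."""
    if rate_Hz < 0:
        raise ValueError("rate must be non-negative")
    if t1_ms <= t0_ms:
        raise ValueError("require t1 > t0")
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate_Hz * (t1_ms - t0_ms) * 1e-3)
    return np.sort(rng.uniform(t0_ms, t1_ms, size=n))


def assign_contexts(
    n_exc: int,
    ctx_fraction: float,
    overlap_fraction: float,
    n_contexts: int,
    seed: int,
) -> ContextAssignment:
    """Randomly assign context target sets among the excitatory neurons.

    Contexts A and B share ``overlap_fraction`` of their targets; any further
    contexts (C, used as the novel renewal context) are disjoint from all
    others.  Reproducible for a fixed seed.
    """
    if not 0 <= ctx_fraction <= 1 or not 0 <= overlap_fraction <= 1:
        raise ValueError("fractions must lie in [0, 1]")
    if n_contexts < 1 or n_contexts > len(CONTEXT_LABELS):
        raise ValueError(f"n_contexts must lie in [1, {len(CONTEXT_LABELS)}]")
    size = int(round(ctx_fraction * n_exc))
    n_shared = int(round(overlap_fraction * size)) if n_contexts >= 2 else 0
    need = size + (size - n_shared) + max(0, n_contexts - 2) * size
    if need > n_exc:
        raise ValueError("context sets exceed the available excitatory neurons")
    rng = np.random.default_rng(seed)
    pool = rng.permutation(n_exc)
    shared = pool[:n_shared]
    rest = pool[n_shared:]
    members: dict[str, np.ndarray] = {}
    offset = 0
    for k in range(min(2, n_contexts)):
        own = rest[offset : offset + size - n_shared]
        offset += size - n_shared
        members[CONTEXT_LABELS[k]] = np.sort(np.concatenate([shared, own])).astype(np.int64)
    for k in range(2, n_contexts):
        members[CONTEXT_LABELS[k]] = np.sort(rest[offset : offset + size]).astype(np.int64)
        offset += size
    return ContextAssignment(members=members, overlap=np.sort(shared).astype(np.int64), n_exc=n_exc)


@dataclass
class PhaseSchedule:
    """Engine-level schedule for one phase (times relative to phase start)."""

    name: str
    duration_ms: float
    cs_onsets_ms: np.ndarray
    cs_duration_ms: float
    context_index: int  # -1 = no context input
    plastic: bool
    inactive_inh_fraction: float
    neuromod_gain: float = 1.0

    @property
    def cs_offsets_ms(self) -> np.ndarray:
        return self.cs_onsets_ms + self.cs_duration_ms


def compile_program(
    phases: list[Phase],
    stim: StimulusParams,
) -> list[PhaseSchedule]:
    """Turn a phase list into deterministic engine schedules.

    CS onsets start after the phase warm-up and repeat at the inter-trial
    interval; the phase ends one ITI after the last onset so each trial has a
    full post-CS window.
    """
    stim.validate()
    if not phases:
        raise ValueError("program must contain at least one phase")
    schedules = []
    for phase in phases:
        phase.validate()
        onsets = phase.warmup_ms + stim.iti_ms * np.arange(phase.n_trials)
        duration = phase.duration_ms
        if duration is None:
            duration = phase.warmup_ms + stim.iti_ms * phase.n_trials
        if phase.n_trials and onsets[-1] + stim.cs_duration_ms >= duration:
            raise ValueError(f"phase {phase.name!r}: CS windows exceed the phase duration")
        ctx_index = -1 if phase.context is None else CONTEXT_LABELS.index(phase.context)
        schedules.append(
            PhaseSchedule(
                name=phase.name,
                duration_ms=float(duration),
                cs_onsets_ms=onsets.astype(float),
                cs_duration_ms=stim.cs_duration_ms,
                context_index=ctx_index,
                plastic=phase.plastic,
                inactive_inh_fraction=phase.inactive_inh_fraction,
                neuromod_gain=phase.neuromod_gain,
            )
        )
    return schedules


def program_frame(phases: list[Phase], stim: StimulusParams) -> pd.DataFrame:
    """Tidy preview of the stimulus program (one row per CS window)."""
    rows = []
    t0 = 0.0
    for sched in compile_program(phases, stim):
        for j, onset in enumerate(sched.cs_onsets_ms):
            rows.append(
                (
                    sched.name,
                    j + 1,
                    t0 + onset,
                    t0 + onset + sched.cs_duration_ms,
                    CONTEXT_LABELS[sched.context_index] if sched.context_index >= 0 else "",
                    sched.plastic,
                )
            )
        if not len(sched.cs_onsets_ms):
            rows.append((sched.name, 0, np.nan, np.nan,
                         CONTEXT_LABELS[sched.context_index] if sched.context_index >= 0 else "",
                         sched.plastic))
        t0 += sched.duration_ms
    return pd.DataFrame(
        rows, columns=["phase", "trial", "cs_start_ms", "cs_end_ms", "context", "plastic"]
    )
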