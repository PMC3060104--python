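"""Shared fixtures.

The expensive network simulations are session-scoped and shared across test
modules: a full-size baseline run, a full-size conditioning+extinction run,
three quarter-scale ABA-renewal repeats, and a dense-connectivity run.
Quarter-scale networks preserve in-degrees (see ``scaled_topology``), which
keeps the operating point of the full model at reduced cost.
"""

import numpy as np
import pytest

from banetsim.params import dense_topology
from banetsim.protocols import (
    ExperimentRunner,
    baseline_spec,
    default_spec,
    run_renewal,
)

SEED = 42
N_REPEATS = 3


@pytest.fixture(scope="session")
def baseline_run():
    """Full-size network, background drive only, 1 s warm-up + 10 s."""
    spec = baseline_spec(seed=SEED, duration_ms=11000.0)
    runner = ExperimentRunner(spec)
    result = runner.run()
    return spec, result


@pytest.fixture(scope="session")
def full_protocol_run():
    """Full-size 2 pre + 5 conditioning + 6 extinction trials, with free-Vm
    shadows on 100 neurons per context group."""
    spec = default_spec(seed=SEED, n_free_vm=100)
    return spec, run_renewal(spec, "A", repeat=0)


@pytest.fixture(scope="session")
def quarter_aba_runs():
    """Three independent quarter-scale ABA-renewal repeats (derived seeds)."""
    spec = default_spec(seed=SEED, scale=0.25)
    return spec, [run_renewal(spec, "A", repeat=rep) for rep in range(N_REPEATS)]


@pytest.fixture(scope="session")
def dense_run():
    """Dense preset (p(E->I) = p(I->I) = 0.5, delays 1-2 ms), 5 s ongoing."""
    spec = baseline_spec(seed=SEED, duration_ms=5000.0)
    spec.topology = dense_topology()
    result = ExperimentRunner(spec).run()
    return spec, result


def evoked_by_group(result, phase_name, window_ms=60.0):
    """Mean per-trial evoked counts of the context-A and context-B sets."""
    from banetsim import analysis

    ne = result.spec.topology.n_exc
    ph = result.phase(phase_name)
    counts = analysis.evoked_response(
        ph.spike_times_ms, ph.spike_ids, ne, ph.cs_onsets_ms, window_ms
    )
    a = result.assignment.members["A"]
    b = result.assignment.members["B"]
    return counts[a].mean(axis=0), counts[b].mean(axis=0)
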