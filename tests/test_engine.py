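"""LIF integration loop: closed-form oracles, invariants, reproducibility."""

import numpy as np
import pytest

from banetsim.engine import (
    init_state,
    lif_isi_constant_input,
    make_neuron_arrays,
    simulate_phase,
)
from banetsim.network import build_network
from banetsim.params import (
    LIFParams,
    PlasticityParams,
    StimulusParams,
    TopologyParams,
    default_lif_exc,
    default_lif_inh,
)
from banetsim.protocols import ExperimentRunner, baseline_spec
from banetsim.stimulus import PhaseSchedule


def _single_neuron_setup(stim, lif=None, n_exc=1, n_inh=0):
    """One unconnected neuron (or a few) with the given external drive."""
    topo = TopologyParams(
        n_exc=n_exc, n_inh=max(n_inh, 1), p_ee=0.0, p_ei=0.0, p_ie=0.0, p_ii=0.0
    )
    net = build_network(topo, seed=0)
    lif_exc = lif or default_lif_exc()
    rng = np.random.default_rng(0)
    neurons = make_neuron_arrays(lif_exc, default_lif_inh(), topo.n_exc, topo.n_inh, 0.1, rng)
    plast = PlasticityParams()
    state = init_state(neurons, plast, n_contexts=1, max_delay_steps=1)
    return net, neurons, plast, state


def _schedule(duration_ms, name="test"):
    return PhaseSchedule(
        name=name,
        duration_ms=duration_ms,
        cs_onsets_ms=np.empty(0),
        cs_duration_ms=50.0,
        context_index=-1,
        plastic=False,
        inactive_inh_fraction=0.0,
    )


def test_zero_input_relaxes_to_rest_without_spikes():
    stim = StimulusParams(bkg_rate_exc_Hz=0.0, bkg_rate_inh_Hz=0.0)
    net, neurons, plast, state = _single_neuron_setup(stim)
    state.V[:] = -60.0
    res = simulate_phase(
        net, neurons, stim, plast, _schedule(200.0), np.zeros((1, 1), np.uint8),
        state, seed=1, vm_ids=np.array([0]),
    )
    assert res.spike_times_ms.size == 0
    assert state.V[0] == pytest.approx(neurons.EL[0], abs=1e-3)
    # free membranes with zero input are flat at rest
    state.V[:] = neurons.EL
    res2 = simulate_phase(
        net, neurons, stim, plast, _schedule(100.0), np.zeros((1, 1), np.uint8),
        state, seed=2, free_ids=np.array([0]),
    )
    np.testing.assert_allclose(res2.free_vm_mV, neurons.EL[0], atol=1e-9)


def test_constant_input_isi_matches_closed_form():
    # near-constant excitatory conductance from a very high-rate, tiny-weight
    # Poisson stream (relative fluctuation ~0.1%); ISI from the LIF closed
    # form t_ref + tau_eff * ln((Vinf - Vreset)/(Vinf - theta)) to < 1%
    g_target = 5.0  # nS, suprathreshold for the default EXC neuron
    rate = 2e6
    lif = LIFParams(threshold_sigma_mV=0.0, refractory_ms=2.0)
    w = g_target / (rate * 1e-3 * lif.tau_exc_ms)
    stim = StimulusParams(bkg_rate_exc_Hz=rate, bkg_rate_inh_Hz=0.0, w_bkg_nS=w)
    net, neurons, plast, state = _single_neuron_setup(stim, lif)
    res = simulate_phase(
        net, neurons, stim, plast, _schedule(2000.0), np.zeros((1, 1), np.uint8),
        state, seed=3,
    )
    own = res.spike_times_ms[res.spike_ids == 0]
    isi = np.diff(own[5:])  # discard transient from rest
    # the oracle uses the effective mean conductance of grid-delivered
    # increments, w * lam_step / (1 - exp(-dt/tau)), which exceeds the
    # continuum value w * r * tau by dt/(2 tau) to first order
    lam_step = rate * 0.1 * 1e-3
    g_eff = w * lam_step / (1.0 - np.exp(-0.1 / lif.tau_exc_ms))
    expected = lif_isi_constant_input(lif, g_eff)
    assert isi.mean() == pytest.approx(expected, rel=0.01)


def test_subthreshold_constant_input_never_spikes():
    lif = LIFParams(threshold_sigma_mV=0.0)
    assert lif_isi_constant_input(lif, 1.0) == np.inf


def test_refractoriness_and_reset(quarter_aba_runs):
    spec, runs = quarter_aba_runs
    tref = spec.lif_exc.refractory_ms
    tref_inh = spec.lif_inh.refractory_ms
    ne = spec.topology.n_exc
    for phase in runs[0].phases:
        order = np.lexsort((phase.spike_times_ms, phase.spike_ids))
        ids = phase.spike_ids[order]
        times = phase.spike_times_ms[order]
        same = ids[1:] == ids[:-1]
        isi = np.diff(times)[same]
        limits = np.where(ids[1:][same] < ne, tref, tref_inh)
        assert np.all(isi >= limits - 1e-9)


def test_bit_identical_for_fixed_seed():
    spec = baseline_spec(seed=5, duration_ms=1500.0, scale=0.05)
    a = ExperimentRunner(spec).run().phases[0]
    b = ExperimentRunner(spec).run().phases[0]
    np.testing.assert_array_equal(a.spike_times_ms, b.spike_times_ms)
    np.testing.assert_array_equal(a.spike_ids, b.spike_ids)
    spec2 = baseline_spec(seed=6, duration_ms=1500.0, scale=0.05)
    c = ExperimentRunner(spec2).run().phases[0]
    assert a.spike_times_ms.size != c.spike_times_ms.size or not np.array_equal(
        a.spike_times_ms, c.spike_times_ms
    )


def test_vm_bounded_by_reversal_potentials():
    stim = StimulusParams()
    net, neurons, plast, state = _single_neuron_setup(stim, n_exc=5, n_inh=2)
    res = simulate_phase(
        net, neurons, stim, plast, _schedule(1000.0), np.zeros((1, 5), np.uint8),
        state, seed=4, vm_ids=np.arange(7),
    )
    assert res.vm_mV.max() <= neurons.e_exc
    assert res.vm_mV.min() >= neurons.e_inh
    # synaptic conductance traces are recorded and never negative
    assert res.gE_nS.shape == res.vm_mV.shape
    assert res.gE_nS.min() >= 0.0 and res.gI_nS.min() >= 0.0
    assert res.gE_nS.max() > 0.0  # background drive present


def test_free_vm_shadow_does_not_perturb_network():
    spec = baseline_spec(seed=9, duration_ms=1000.0, scale=0.05)
    plain = ExperimentRunner(spec).run().phases[0]
    spec_free = baseline_spec(seed=9, duration_ms=1000.0, scale=0.05)
    spec_free.n_free_vm = 0  # free ids supplied manually below
    runner = ExperimentRunner(spec_free)
    runner._free_ids = np.arange(10, dtype=np.int64)
    shadowed = runner.run().phases[0]
    np.testing.assert_array_equal(plain.spike_times_ms, shadowed.spike_times_ms)
    np.testing.assert_array_equal(plain.spike_ids, shadowed.spike_ids)
    assert shadowed.free_vm_mV.shape[1] == 10


def test_feedforward_rate_independent_of_population_size():
    # without recurrent edges the rate is a pure function of the external
    # drive: two disconnected populations of different size agree
    rates = []
    for n in (100, 400):
        spec = baseline_spec(seed=11, duration_ms=4000.0)
        spec.topology = TopologyParams(n_exc=n, n_inh=10, p_ee=0, p_ei=0, p_ie=0, p_ii=0)
        res = ExperimentRunner(spec).run().phases[0]
        mask = (res.spike_times_ms > 500) & (res.spike_ids < n)
        rates.append(mask.sum() / (n * 3.5))
    assert rates[0] == pytest.approx(rates[1], rel=0.25)


def test_synaptic_delay_respected():
    # strong E->E drive: the postsynaptic neuron fires only after the
    # presynaptic spike has traversed the delay
    topo = TopologyParams(n_exc=2, n_inh=1, p_ee=1.0, p_ei=0, p_ie=0, p_ii=0,
                          w_ee_nS=200.0, delay_min_ms=1.5, delay_max_ms=1.5)
    net = build_network(topo, seed=0)
    lif = LIFParams(threshold_sigma_mV=0.0)
    rng = np.random.default_rng(0)
    neurons = make_neuron_arrays(lif, default_lif_inh(), 2, 1, 0.1, rng)
    plast = PlasticityParams()
    state = init_state(neurons, plast, 1, int(net.delay_steps.max()))
    # drive only neuron 0 via its private background stream: make neuron 1's
    # drive zero by setting lam per-neuron is not exposed, so drive both but
    # raise neuron 1's threshold out of reach of the background alone
    neurons.theta[1] = -25.0
    stim = StimulusParams(bkg_rate_exc_Hz=4000.0, bkg_rate_inh_Hz=0.0, w_bkg_nS=1.2)
    res = simulate_phase(
        net, neurons, stim, plast, _schedule(500.0), np.zeros((1, 2), np.uint8),
        state, seed=7,
    )
    t0 = res.spike_times_ms[res.spike_ids == 0]
    t1 = res.spike_times_ms[res.spike_ids == 1]
    assert t0.size > 0 and t1.size > 0
    # every neuron-1 spike follows a neuron-0 spike by at least the delay
    # (and by no more than a few membrane time constants)
    for t in t1:
        preceding = t0[(t0 <= t - 1.5) & (t0 > t - 10.0)]
        assert preceding.size > 0


def test_kernel_plasticity_probe_behaviour():
    # members of the active context with CS potentiate; non-members depress;
    # weights at the upper bound stay exactly there; probe-off leaves all
    # weights untouched
    topo = TopologyParams(n_exc=40, n_inh=1, p_ee=0, p_ei=0, p_ie=0, p_ii=0)
    net = build_network(topo, seed=0)
    rng = np.random.default_rng(0)
    neurons = make_neuron_arrays(default_lif_exc(), default_lif_inh(), 40, 1, 0.1, rng)
    plast = PlasticityParams()
    stim = StimulusParams()
    member = np.zeros((1, 40), np.uint8)
    member[0, :20] = 1
    sched = PhaseSchedule(
        name="probe", duration_ms=1000.0, cs_onsets_ms=np.array([500.0]),
        cs_duration_ms=50.0, context_index=0, plastic=True,
        inactive_inh_fraction=0.0,
    )
    state = init_state(neurons, plast, 1, 1)
    state.w_cs[30:] = plast.w_max_nS  # non-members pinned at the bound...
    res = simulate_phase(net, neurons, stim, plast, sched, member, state, seed=1)
    assert np.all(res.w_cs_log[1, :20] > res.w_cs_log[0, :20])  # LTP members
    assert np.all(res.w_ctx_log[1, :20, 0] > res.w_ctx_log[0, :20, 0])
    assert np.all(res.w_cs_log[1, 20:30] < res.w_cs_log[0, 20:30])  # LTD others
    # ...depression moves them off w_max, but an LTP-side probe at w_max would
    # give exactly zero increment; check via a member pinned at the bound
    state2 = init_state(neurons, plast, 1, 1)
    state2.w_cs[:20] = plast.w_max_nS
    state2.w_ctx[:20, 0] = plast.w_max_nS
    res2 = simulate_phase(net, neurons, stim, plast, sched, member, state2, seed=1)
    np.testing.assert_array_equal(res2.w_cs_log[1, :20], plast.w_max_nS)
    # probe disabled: no weight changes at all
    sched_off = PhaseSchedule(
        name="off", duration_ms=1000.0, cs_onsets_ms=np.array([500.0]),
        cs_duration_ms=50.0, context_index=0, plastic=False,
        inactive_inh_fraction=0.0,
    )
    state3 = init_state(neurons, plast, 1, 1)
    res3 = simulate_phase(net, neurons, stim, plast, sched_off, member, state3, seed=1)
    np.testing.assert_array_equal(res3.w_cs_log[1], res3.w_cs_log[0])
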