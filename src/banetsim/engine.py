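"""Clock-driven simulation of the conductance-based LIF network.

The integration uses exponential updates for the linear sub-steps at a fixed
dt (default 0.1 ms): synaptic conductances decay exactly, and the membrane is
advanced with the total conductance held constant over the step.  Spikes are
delivered through a ring buffer of per-neuron conductance increments indexed
by the per-edge delay (rounded to the dt grid).  External Poisson input is
drawn on the fly inside the kernel from the phase seed, one independent
stream per neuron per source class, which makes a phase bit-reproducible for
a fixed (network, state, schedule, seed).

Plasticity tags (c, h) are accumulated incrementally inside the kernel using
the same exponential decay as the closed form in :mod:`banetsim.plasticity`,
and the CS-offset probe applies the identical update rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from banetsim.network import NetworkTopology
from banetsim.params import LIFParams, PlasticityParams, StimulusParams
from banetsim.stimulus import PhaseSchedule

__all__ = [
    "NeuronArrays",
    "NetworkState",
    "PhaseResult",
    "make_neuron_arrays",
    "init_state",
    "simulate_phase",
    "lif_isi_constant_input",
]

_STATUS_MESSAGES = {
    1: "spike buffer overflow: raise spike_capacity",
    2: "non-finite membrane potential encountered (diverging simulation)",
}


@dataclass
class NeuronArrays:
    """Per-neuron membrane parameters expanded from the class-level configs."""

    n_exc: int
    n_inh: int
    gL: np.ndarray
    cap: np.ndarray
    EL: np.ndarray
    theta: np.ndarray
    reset: np.ndarray
    tref_steps: np.ndarray
    dec_gE: np.ndarray  # per-neuron conductance decay factors per dt
    dec_gI: np.ndarray
    e_exc: float
    e_inh: float

    @property
    def n_total(self) -> int:
        return self.n_exc + self.n_inh


def make_neuron_arrays(
    lif_exc: LIFParams,
    lif_inh: LIFParams,
    n_exc: int,
    n_inh: int,
    dt_ms: float,
    rng: np.random.Generator,
) -> NeuronArrays:
    """Expand class parameters to arrays; thresholds are drawn per neuron."""
    lif_exc.validate()
    lif_inh.validate()
    if lif_exc.e_exc_mV != lif_inh.e_exc_mV or lif_exc.e_inh_mV != lif_inh.e_inh_mV:
        raise ValueError("reversal potentials must agree across classes")

    def expand(val_e, val_i):
        return np.concatenate([np.full(n_exc, val_e, dtype=float), np.full(n_inh, val_i, dtype=float)])

    theta = np.concatenate(
        [lif_exc.sample_thresholds(n_exc, rng), lif_inh.sample_thresholds(n_inh, rng)]
    )
    return NeuronArrays(
        n_exc=n_exc,
        n_inh=n_inh,
        gL=expand(lif_exc.leak_nS, lif_inh.leak_nS),
        cap=expand(lif_exc.capacitance_pF, lif_inh.capacitance_pF),
        EL=expand(lif_exc.rest_mV, lif_inh.rest_mV),
        theta=theta,
        reset=expand(lif_exc.reset_mV, lif_inh.reset_mV),
        tref_steps=np.concatenate(
            [
                np.full(n_exc, int(round(lif_exc.refractory_ms / dt_ms)), dtype=np.int32),
                np.full(n_inh, int(round(lif_inh.refractory_ms / dt_ms)), dtype=np.int32),
            ]
        ),
        dec_gE=expand(math.exp(-dt_ms / lif_exc.tau_exc_ms), math.exp(-dt_ms / lif_inh.tau_exc_ms)),
        dec_gI=expand(math.exp(-dt_ms / lif_exc.tau_inh_ms), math.exp(-dt_ms / lif_inh.tau_inh_ms)),
        e_exc=lif_exc.e_exc_mV,
        e_inh=lif_exc.e_inh_mV,
    )


@dataclass
class NetworkState:
    """Complete dynamical state: carries over between phases and checkpoints."""

    V: np.ndarray
    gE: np.ndarray
    gI: np.ndarray
    refr: np.ndarray  # remaining refractory steps
    buf: np.ndarray  # (D, n_total, 2) in-flight delayed conductance increments
    c: np.ndarray  # (n_exc,) CS tags
    h: np.ndarray  # (n_exc, n_ctx) context tags
    w_cs: np.ndarray  # (n_exc,) plastic CS weights
    w_ctx: np.ndarray  # (n_exc, n_ctx) plastic context weights
    t_ms: float = 0.0

    def copy(self) -> "NetworkState":
        return NetworkState(
            V=self.V.copy(),
            gE=self.gE.copy(),
            gI=self.gI.copy(),
            refr=self.refr.copy(),
            buf=self.buf.copy(),
            c=self.c.copy(),
            h=self.h.copy(),
            w_cs=self.w_cs.copy(),
            w_ctx=self.w_ctx.copy(),
            t_ms=self.t_ms,
        )

    def reset_traces(self) -> None:
        """Zero the eligibility tags (applied between phases: the inter-phase
        gap is long relative to the tag time constants)."""
        self.c[:] = 0.0
        self.h[:] = 0.0


def init_state(
    neurons: NeuronArrays,
    plasticity: PlasticityParams,
    n_contexts: int,
    max_delay_steps: int,
) -> NetworkState:
    n = neurons.n_total
    return NetworkState(
        V=neurons.EL.copy(),
        gE=np.zeros(n),
        gI=np.zeros(n),
        refr=np.zeros(n, dtype=np.int32),
        buf=np.zeros((max(2, max_delay_steps + 1), n, 2)),
        c=np.zeros(neurons.n_exc),
        h=np.zeros((neurons.n_exc, n_contexts)),
        w_cs=np.full(neurons.n_exc, plasticity.w_cs_init_nS),
        w_ctx=np.full((neurons.n_exc, n_contexts), plasticity.w_ctx_init_nS),
    )


@dataclass
class PhaseResult:
    """Raw recordings from one simulated phase (times absolute, ms)."""

    name: str
    t0_ms: float
    duration_ms: float
    context_index: int
    cs_onsets_ms: np.ndarray  # absolute
    cs_duration_ms: float
    spike_times_ms: np.ndarray
    spike_ids: np.ndarray
    probe_times_ms: np.ndarray  # absolute CS offsets (weights logged there)
    w_cs_log: np.ndarray  # (n_offsets + 1, n_exc); row 0 = phase entry
    w_ctx_log: np.ndarray  # (n_offsets + 1, n_exc, n_ctx)
    vm_ids: np.ndarray
    vm_times_ms: np.ndarray
    vm_mV: np.ndarray  # (n_samples, n_recorded)
    gE_nS: np.ndarray  # (n_samples, n_recorded) synaptic conductance traces
    gI_nS: np.ndarray
    free_ids: np.ndarray
    free_vm_mV: np.ndarray  # (n_samples, n_free)

    def spikes_of(self, ids: np.ndarray) -> np.ndarray:
        mask = np.isin(self.spike_ids, ids)
        return self.spike_times_ms[mask]


@njit(cache=True)
def _run_kernel(
    n_steps,
    dt,
    n_exc,
    n_total,
    gL,
    cap,
    EL,
    EE,
    EI,
    theta,
    Vreset,
    tref_steps,
    dec_gE,
    dec_gI,
    indptr,
    tgt,
    wsyn,
    dstep,
    V,
    gE,
    gI,
    refr,
    buf,
    c,
    h,
    w_cs,
    w_ctx,
    lam_bkg,
    lam_cs,
    lam_ctx,
    w_bkg,
    w_cs_inh,
    ctx_member,
    active_ctx,
    cs_start,
    cs_end,
    probe_on,
    inc,
    dec_c,
    dec_h,
    th_low,
    th_high,
    a1m,
    a2,
    wmin,
    wmax,
    can_spike,
    spike_step,
    spike_id,
    w_cs_log,
    w_ctx_log,
    vm_ids,
    vm_every,
    vm_out,
    ge_out,
    gi_out,
    free_ids,
    Vfree,
    free_out,
    seed,
):
    np.random.seed(seed)
    D = buf.shape[0]
    n_ctx = w_ctx.shape[1]
    n_cs = cs_start.shape[0]
    max_spikes = spike_step.shape[0]
    n_spk = 0
    cs_ptr = 0
    status = 0
    for step in range(n_steps):
        # ---- CS-offset probe ---------------------------------------------
        if cs_ptr < n_cs and step == cs_end[cs_ptr]:
            if probe_on == 1:
                for i in range(n_exc):
                    has_ctx = False
                    for k in range(n_ctx):
                        if ctx_member[k, i] == 1:
                            has_ctx = True
                            s = c[i] + h[i, k]
                            if s > th_high:
                                w_cs[i] += a1m * (wmax - w_cs[i])
                                w_ctx[i, k] += a1m * (wmax - w_ctx[i, k])
                            elif s > th_low:
                                w_cs[i] -= a2 * (w_cs[i] - wmin)
                                w_ctx[i, k] -= a2 * (w_ctx[i, k] - wmin)
                    if not has_ctx:
                        s = c[i]
                        if s > th_high:
                            w_cs[i] += a1m * (wmax - w_cs[i])
                        elif s > th_low:
                            w_cs[i] -= a2 * (w_cs[i] - wmin)
            row = cs_ptr + 1
            for i in range(n_exc):
                w_cs_log[row, i] = w_cs[i]
                for k in range(n_ctx):
                    w_ctx_log[row, i, k] = w_ctx[i, k]
            cs_ptr += 1

        cs_on = cs_ptr < n_cs and cs_start[cs_ptr] <= step

        # ---- per-neuron update -------------------------------------------
        slot = step % D
        for i in range(n_total):
            gE[i] = gE[i] * dec_gE[i] + buf[slot, i, 0]
            gI[i] = gI[i] * dec_gI[i] + buf[slot, i, 1]
            buf[slot, i, 0] = 0.0
            buf[slot, i, 1] = 0.0
            kb = np.random.poisson(lam_bkg[i])
            if kb > 0:
                gE[i] += kb * w_bkg
            if i < n_exc:
                c[i] *= dec_c
                for k in range(n_ctx):
                    h[i, k] *= dec_h
                if cs_on and lam_cs > 0.0:
                    kc = np.random.poisson(lam_cs)
                    if kc > 0:
                        gE[i] += kc * w_cs[i]
                        c[i] += kc * inc
                if active_ctx >= 0 and ctx_member[active_ctx, i] == 1 and lam_ctx > 0.0:
                    kx = np.random.poisson(lam_ctx)
                    if kx > 0:
                        gE[i] += kx * w_ctx[i, active_ctx]
                        h[i, active_ctx] += kx * inc
            else:
                if cs_on and lam_cs > 0.0:
                    kc = np.random.poisson(lam_cs)
                    if kc > 0:
                        gE[i] += kc * w_cs_inh

            if refr[i] > 0:
                refr[i] -= 1
                V[i] = Vreset[i]
            else:
                gtot = gL[i] + gE[i] + gI[i]
                Vinf = (gL[i] * EL[i] + gE[i] * EE + gI[i] * EI) / gtot
                V[i] = Vinf + (V[i] - Vinf) * math.exp(-dt * gtot / cap[i])
                if V[i] >= theta[i] and can_spike[i] == 1:
                    if n_spk >= max_spikes:
                        status = 1
                        break
                    spike_step[n_spk] = step
                    spike_id[n_spk] = i
                    n_spk += 1
                    V[i] = Vreset[i]
                    refr[i] = tref_steps[i]
                    is_exc = i < n_exc
                    for e in range(indptr[i], indptr[i + 1]):
                        j = tgt[e]
                        s = (step + dstep[e]) % D
                        if is_exc:
                            buf[s, j, 0] += wsyn[e]
                        else:
                            buf[s, j, 1] += wsyn[e]
        if status != 0:
            break

        # ---- shadow free membranes (thresholding disabled) ---------------
        for f in range(free_ids.shape[0]):
            i = free_ids[f]
            gtot = gL[i] + gE[i] + gI[i]
            Vinf = (gL[i] * EL[i] + gE[i] * EE + gI[i] * EI) / gtot
            Vfree[f] = Vinf + (Vfree[f] - Vinf) * math.exp(-dt * gtot / cap[i])

        # ---- recording ----------------------------------------------------
        if vm_every > 0 and step % vm_every == 0:
            samp = step // vm_every
            for r in range(vm_ids.shape[0]):
                vm_out[samp, r] = V[vm_ids[r]]
                ge_out[samp, r] = gE[vm_ids[r]]
                gi_out[samp, r] = gI[vm_ids[r]]
            for f in range(free_ids.shape[0]):
                free_out[samp, f] = Vfree[f]

        if step % 5000 == 0:
            ok = True
            for i in range(n_total):
                if not math.isfinite(V[i]):
                    ok = False
                    break
            if not ok:
                status = 2
                break

    return n_spk, status


def simulate_phase(
    net: NetworkTopology,
    neurons: NeuronArrays,
    stim: StimulusParams,
    plasticity: PlasticityParams,
    schedule: PhaseSchedule,
    ctx_member: np.ndarray,
    state: NetworkState,
    seed: int,
    dt_ms: float = 0.1,
    vm_ids: np.ndarray | None = None,
    free_ids: np.ndarray | None = None,
    vm_sample_ms: float = 1.0,
    inactive_inh_ids: np.ndarray | None = None,
    spike_capacity: int | None = None,
) -> PhaseResult:
    """Run one phase; ``state`` is advanced in place and time accumulates.

    ``ctx_member`` is the (n_contexts, n_exc) uint8 membership matrix from
    :meth:`banetsim.stimulus.ContextAssignment.membership_matrix`.  The phase
    draws all randomness from ``seed``; two calls with identical inputs
    produce bit-identical spike records.
    """
    stim.validate()
    plasticity.validate()
    n_exc, n_total = neurons.n_exc, neurons.n_total
    n_ctx = state.w_ctx.shape[1]
    if ctx_member.shape != (n_ctx, n_exc):
        raise ValueError("ctx_member shape must be (n_contexts, n_exc)")
    if schedule.context_index >= n_ctx:
        raise ValueError("phase references a context index beyond the state's contexts")
    n_steps = int(round(schedule.duration_ms / dt_ms))
    cs_start = np.rint(schedule.cs_onsets_ms / dt_ms).astype(np.int64)
    cs_end = np.rint(schedule.cs_offsets_ms / dt_ms).astype(np.int64)
    if len(cs_end) and cs_end[-1] >= n_steps:
        raise ValueError("last CS offset must fall inside the phase")

    lam_bkg = np.concatenate(
        [
            np.full(n_exc, stim.bkg_rate_exc_Hz * dt_ms * 1e-3),
            np.full(neurons.n_inh, stim.bkg_rate_inh_Hz * dt_ms * 1e-3),
        ]
    )
    lam_cs = stim.cs_rate_Hz * dt_ms * 1e-3
    lam_ctx = stim.ctx_rate_Hz * dt_ms * 1e-3

    can_spike = np.ones(n_total, dtype=np.uint8)
    if inactive_inh_ids is not None and len(inactive_inh_ids):
        can_spike[np.asarray(inactive_inh_ids, dtype=np.int64)] = 0

    if spike_capacity is None:
        # generous headroom over the expected regime (EXC ~ few Hz, INH tens of Hz)
        spike_capacity = int(
            schedule.duration_ms * 1e-3 * (n_exc * 20 + neurons.n_inh * 150) + 100_000
        )
    spike_step = np.empty(spike_capacity, dtype=np.int64)
    spike_id = np.empty(spike_capacity, dtype=np.int32)

    n_probe_rows = len(cs_end) + 1
    w_cs_log = np.empty((n_probe_rows, n_exc))
    w_ctx_log = np.empty((n_probe_rows, n_exc, n_ctx))
    w_cs_log[0] = state.w_cs
    w_ctx_log[0] = state.w_ctx

    vm_ids = np.asarray(vm_ids if vm_ids is not None else [], dtype=np.int64)
    free_ids = np.asarray(free_ids if free_ids is not None else [], dtype=np.int64)
    vm_every = int(round(vm_sample_ms / dt_ms)) if (len(vm_ids) or len(free_ids)) else 0
    n_samp = (n_steps + vm_every - 1) // vm_every if vm_every else 0
    vm_out = np.empty((n_samp, len(vm_ids)))
    ge_out = np.empty((n_samp, len(vm_ids)))
    gi_out = np.empty((n_samp, len(vm_ids)))
    free_out = np.empty((n_samp, len(free_ids)))
    Vfree = state.V[free_ids].copy() if len(free_ids) else np.empty(0)

    n_spk, status = _run_kernel(
        n_steps,
        dt_ms,
        n_exc,
        n_total,
        neurons.gL,
        neurons.cap,
        neurons.EL,
        neurons.e_exc,
        neurons.e_inh,
        neurons.theta,
        neurons.reset,
        neurons.tref_steps,
        neurons.dec_gE,
        neurons.dec_gI,
        net.indptr,
        net.targets,
        net.weights_nS,
        net.delay_steps,
        state.V,
        state.gE,
        state.gI,
        state.refr,
        state.buf,
        state.c,
        state.h,
        state.w_cs,
        state.w_ctx,
        lam_bkg,
        lam_cs,
        lam_ctx,
        stim.w_bkg_nS,
        stim.w_cs_inh_nS,
        np.ascontiguousarray(ctx_member, dtype=np.uint8),
        schedule.context_index,
        cs_start,
        cs_end,
        1 if schedule.plastic else 0,
        plasticity.trace_increment,
        math.exp(-dt_ms / plasticity.tau_c_ms),
        math.exp(-dt_ms / plasticity.tau_h_ms),
        plasticity.theta_low,
        plasticity.theta_high,
        plasticity.a1 * plasticity.m * schedule.neuromod_gain,
        plasticity.a2,
        plasticity.w_min_nS,
        plasticity.w_max_nS,
        can_spike,
        spike_step,
        spike_id,
        w_cs_log,
        w_ctx_log,
        vm_ids,
        vm_every,
        vm_out,
        ge_out,
        gi_out,
        free_ids,
        Vfree,
        free_out,
        int(seed) % (2**31 - 1),
    )
    if status != 0:
        raise RuntimeError(f"simulation aborted at t={state.t_ms:.1f} ms: {_STATUS_MESSAGES[status]}")

    t0 = state.t_ms
    result = PhaseResult(
        name=schedule.name,
        t0_ms=t0,
        duration_ms=schedule.duration_ms,
        context_index=schedule.context_index,
        cs_onsets_ms=t0 + schedule.cs_onsets_ms,
        cs_duration_ms=schedule.cs_duration_ms,
        spike_times_ms=t0 + spike_step[:n_spk] * dt_ms,
        spike_ids=spike_id[:n_spk].copy(),
        probe_times_ms=t0 + schedule.cs_offsets_ms,
        w_cs_log=w_cs_log,
        w_ctx_log=w_ctx_log,
        vm_ids=vm_ids,
        vm_times_ms=t0 + np.arange(n_samp) * (vm_every * dt_ms) if vm_every else np.empty(0),
        vm_mV=vm_out,
        gE_nS=ge_out,
        gI_nS=gi_out,
        free_ids=free_ids,
        free_vm_mV=free_out,
    )
    state.t_ms = t0 + schedule.duration_ms
    return result


def lif_isi_constant_input(
    params: LIFParams, g_exc_nS: float, v_start_mV: float | None = None
) -> float:
    """Closed-form inter-spike interval of a LIF under constant excitatory
    conductance: t_ref + tau_eff * ln((V_inf - V_reset) / (V_inf - theta)).

    Used as the independent oracle for the integration loop.
    """
    g_tot = params.leak_nS + g_exc_nS
    v_inf = (params.leak_nS * params.rest_mV + g_exc_nS * params.e_exc_mV) / g_tot
    if v_inf <= params.threshold_mV:
        return math.inf
    tau_eff = params.capacitance_pF / g_tot
    v0 = params.reset_mV if v_start_mV is None else v_start_mV
    return params.refractory_ms + tau_eff * math.log((v_inf - v0) / (v_inf - params.threshold_mV))
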