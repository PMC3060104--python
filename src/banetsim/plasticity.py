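"""Eligibility-trace plasticity on CS and contextual afferents.

Each excitatory neuron maintains a CS tag ``c`` and one context tag ``h`` per
context afferent it receives.  Presynaptic spikes increment the corresponding
tag by a fixed amount; between spikes tags relax exponentially to zero.  At
the offset of every CS presentation the tags are probed and the CS / context
synapse weights of each neuron are updated jointly (calcium-control logic):
the combined signal c + h above ``theta_high`` potentiates both synapses,
between ``theta_low`` and ``theta_high`` depresses both, and below
``theta_low`` leaves them untouched.  Soft bounds make the step size vanish
at ``w_min`` / ``w_max``.

The fast simulation kernel (:mod:`banetsim.engine`) carries the same tag and
update arithmetic incrementally; the event-based closed forms here are the
reference implementation used for testing and offline analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from banetsim.params import PlasticityParams

__all__ = [
    "PlasticSynapseState",
    "trace_at",
    "trace_time_course",
    "probe_pair",
    "probe_update",
]

NO_CHANGE, LTP, LTD = 0, 1, -1


@dataclass
class PlasticSynapseState:
    """Weight plus tags for one (CS synapse, context synapse) pair."""

    w_cs: float
    w_ctx: float
    c: float = 0.0
    h: float = 0.0
    w_cs_minus: float = field(default=np.nan)  # weights before the last probe
    w_ctx_minus: float = field(default=np.nan)


def trace_at(spike_times_ms: np.ndarray, t_ms: float, tau_ms: float, increment: float) -> float:
    """Closed-form tag value at time t for a list of presynaptic spike times.

    c(t) = increment * sum_i exp(-(t - t_i) / tau) over spikes with t_i <= t.
    """
    if tau_ms <= 0:
        raise ValueError("tau must be positive")
    times = np.asarray(spike_times_ms, dtype=float)
    past = times[times <= t_ms]
    return float(increment * np.exp(-(t_ms - past) / tau_ms).sum())


def trace_time_course(
    spike_times_ms: np.ndarray, t_grid_ms: np.ndarray, tau_ms: float, increment: float
) -> np.ndarray:
    """Tag value evaluated on a time grid (vectorised closed form)."""
    return np.array([trace_at(spike_times_ms, t, tau_ms, increment) for t in np.asarray(t_grid_ms)])


def probe_pair(w_cs: float, w_ctx: float, c: float, h: float, params: PlasticityParams):
    """Probe one synapse pair; returns (w_cs', w_ctx', direction).

    direction is +1 (LTP), -1 (LTD) or 0 -- a single probe moves a pair in at
    most one direction.
    """
    s = c + h
    if s > params.theta_high:
        step = params.a1 * params.m
        return (
            w_cs + step * (params.w_max_nS - w_cs),
            w_ctx + step * (params.w_max_nS - w_ctx),
            LTP,
        )
    if s > params.theta_low:
        return (
            w_cs - params.a2 * (w_cs - params.w_min_nS),
            w_ctx - params.a2 * (w_ctx - params.w_min_nS),
            LTD,
        )
    return w_cs, w_ctx, NO_CHANGE


def probe_update(
    w_cs: np.ndarray,
    w_ctx: np.ndarray,
    c: np.ndarray,
    h: np.ndarray,
    ctx_member: np.ndarray,
    params: PlasticityParams,
):
    """Vectorised CS-offset probe over all excitatory neurons (reference).

    Mirrors the in-kernel update: for every context afferent a neuron
    receives, the pair (CS synapse, that context synapse) is probed with
    signal c + h[:, k]; neurons without any context afferent probe the CS
    synapse alone with signal c.  Arrays are modified and returned as copies.

    Parameters
    ----------
    w_cs : (n_exc,) CS weights.
    w_ctx : (n_exc, n_ctx) context weights.
    c, h : tags, shapes (n_exc,) and (n_exc, n_ctx).
    ctx_member : (n_ctx, n_exc) uint8 membership matrix.
    """
    params.validate()
    w_cs = w_cs.copy()
    w_ctx = w_ctx.copy()
    n_exc, n_ctx = w_ctx.shape
    step1 = params.a1 * params.m
    for k in range(n_ctx):
        mem = ctx_member[k].astype(bool)
        s = c + h[:, k]
        ltp = mem & (s > params.theta_high)
        ltd = mem & (s > params.theta_low) & ~ltp
        w_cs[ltp] += step1 * (params.w_max_nS - w_cs[ltp])
        w_ctx[ltp, k] += step1 * (params.w_max_nS - w_ctx[ltp, k])
        w_cs[ltd] -= params.a2 * (w_cs[ltd] - params.w_min_nS)
        w_ctx[ltd, k] -= params.a2 * (w_ctx[ltd, k] - params.w_min_nS)
    none = ~ctx_member.astype(bool).any(axis=0)
    ltp = none & (c > params.theta_high)
    ltd = none & (c > params.theta_low) & ~ltp
    w_cs[ltp] += step1 * (params.w_max_nS - w_cs[ltp])
    w_cs[ltd] -= params.a2 * (w_cs[ltd] - params.w_min_nS)
    return w_cs, w_ctx
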