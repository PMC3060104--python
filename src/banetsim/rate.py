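"""Two-population mean-field (firing-rate) model of the basal amygdala.

Populations A and B obey Wilson-Cowan dynamics with mutual inhibition:

    tau_X dX/dt = -X + (k_X - r_X * X) * S(I_X + eta(t))

where S is a logistic transfer function with steepness ``p`` and midpoint
``theta``, ``k_X`` is the maximum rate, ``r_X`` captures refractoriness and
``eta`` is zero-mean Gaussian noise.  The input sum is

    I_X = w_X_CS * CS(t) + w_X_CTX * CTX_X(t) - w_inh * X_other + bkg

CS input arrives as short (50 ms) pulses to both populations; context input
is tonic and population-specific.  CS and context weights onto a population
grow additively (by the learning rate) at the offset of every CS pulse during
which that population's context was active -- coincidence learning with no
depotentiation, so weights never decrease in this model.

With noise off, both populations start identical; the only symmetry-breaking
is which population receives context input in which phase.  Population A is
conventionally the one conditioned first ("fear" population) and B the one
recruited during extinction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from banetsim.params import derive_seed

__all__ = [
    "RateParams",
    "RateModelState",
    "RateStimulus",
    "RatePhase",
    "sigmoid_transfer",
    "step_rate_dynamics",
    "update_rate_weights",
    "run_rate_phase",
    "run_rate_protocol",
    "default_rate_protocol",
]


@dataclass
class RateParams:
    tau_A_ms: float = 10.0
    tau_B_ms: float = 10.0
    k_A: float = 1.0  # maximum (normalised) firing rate
    k_B: float = 1.0
    r_A: float = 1.0  # refractoriness coefficient
    r_B: float = 1.0
    sigmoid_p: float = 5.0
    sigmoid_theta: float = 1.2
    w_inh_AB: float = 1.5  # magnitude of inhibition B exerts on A
    w_inh_BA: float = 1.5  # magnitude of inhibition A exerts on B
    a_A: float = 0.05  # additive learning rate, population A afferents
    a_B: float = 0.05
    noise_sigma: float = 0.1
    bkg_level: float = 0.0

    def validate(self) -> None:
        if self.tau_A_ms <= 0 or self.tau_B_ms <= 0:
            raise ValueError("time constants must be positive")
        if self.k_A <= 0 or self.k_B <= 0:
            raise ValueError("maximum rates must be positive")
        if self.r_A < 0 or self.r_B < 0:
            raise ValueError("refractoriness coefficients must be non-negative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.sigmoid_p <= 0:
            raise ValueError("sigmoid steepness must be positive")


@dataclass
class RateModelState:
    act_A: float = 0.0
    act_B: float = 0.0
    w_A_CS: float = 0.05
    w_B_CS: float = 0.05
    w_A_CTX: float = 0.05
    w_B_CTX: float = 0.05
    t_ms: float = 0.0

    def copy(self) -> "RateModelState":
        return replace(self)


@dataclass
class RateStimulus:
    """Stimulus configuration for one phase (fixed context)."""

    cs_times_ms: tuple[float, ...] = ()
    cs_duration_ms: float = 50.0
    cs_amplitude: float = 3.0
    context: str | None = "A"  # which population receives tonic context input
    ctx_amplitude: float = 1.0

    def validate(self) -> None:
        if self.cs_duration_ms <= 0:
            raise ValueError("cs_duration_ms must be positive")
        onsets = np.sort(np.asarray(self.cs_times_ms, dtype=float))
        if onsets.size > 1 and np.any(np.diff(onsets) < self.cs_duration_ms):
            raise ValueError("CS pulses must not overlap")
        if self.context not in (None, "A", "B"):
            raise ValueError("context must be 'A', 'B' or None")

    def cs_active(self, t_ms: float) -> bool:
        for t0 in self.cs_times_ms:
            if t0 <= t_ms < t0 + self.cs_duration_ms:
                return True
        return False


@dataclass
class RatePhase:
    name: str
    context: str | None
    n_trials: int
    plastic: bool = True


def sigmoid_transfer(x, p: float, theta: float):
    """Logistic transfer S(x) = 1 / (1 + exp(-p (x - theta))).

    Strictly increasing, bounded in (0, 1), maximum slope p/4 at x = theta.
    """
    if p <= 0:
        raise ValueError("sigmoid steepness p must be positive")
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("sigmoid input must be finite")
    with np.errstate(over="ignore"):  # saturates cleanly to 0
        out = 1.0 / (1.0 + np.exp(-p * (x - theta)))
    return float(out) if out.ndim == 0 else out


def _inputs(state: RateModelState, params: RateParams, stim: RateStimulus, t_ms: float):
    cs = stim.cs_amplitude if stim.cs_active(t_ms) else 0.0
    ctx_A = stim.ctx_amplitude if stim.context == "A" else 0.0
    ctx_B = stim.ctx_amplitude if stim.context == "B" else 0.0
    I_A = state.w_A_CS * cs + state.w_A_CTX * ctx_A - params.w_inh_AB * state.act_B + params.bkg_level
    I_B = state.w_B_CS * cs + state.w_B_CTX * ctx_B - params.w_inh_BA * state.act_A + params.bkg_level
    return I_A, I_B


def step_rate_dynamics(
    state: RateModelState,
    params: RateParams,
    stim: RateStimulus,
    dt_ms: float,
    rng: np.random.Generator | None = None,
) -> RateModelState:
    """One (stochastic) Euler step of the population dynamics.

    Noise enters the input sum inside the transfer function, scaled by
    sqrt(dt); with ``noise_sigma = 0`` the step is deterministic.  Activities
    remain in [0, k_X] because the leak pulls towards 0 and the refractory
    term (k - r X) caps growth.
    """
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    if dt_ms >= min(params.tau_A_ms, params.tau_B_ms):
        raise ValueError("dt must be well below the population time constants")
    I_A, I_B = _inputs(state, params, stim, state.t_ms)
    if params.noise_sigma > 0 and rng is not None:
        sq = np.sqrt(dt_ms)
        I_A += params.noise_sigma * sq * rng.standard_normal()
        I_B += params.noise_sigma * sq * rng.standard_normal()
    S_A = sigmoid_transfer(I_A, params.sigmoid_p, params.sigmoid_theta)
    S_B = sigmoid_transfer(I_B, params.sigmoid_p, params.sigmoid_theta)
    dA = (-state.act_A + (params.k_A - params.r_A * state.act_A) * S_A) * dt_ms / params.tau_A_ms
    dB = (-state.act_B + (params.k_B - params.r_B * state.act_B) * S_B) * dt_ms / params.tau_B_ms
    new = state.copy()
    new.act_A = state.act_A + dA
    new.act_B = state.act_B + dB
    new.t_ms = state.t_ms + dt_ms
    return new


def update_rate_weights(
    state: RateModelState,
    params: RateParams,
    cs_active: bool,
    ctx_on: str | None,
) -> RateModelState:
    """Additive coincidence update, applied once per CS pulse at its offset.

    The CS and context weights of a population increase by its learning rate
    only when the CS and that population's context input were present
    simultaneously.  There is no depotentiation: weights never decrease.
    """
    new = state.copy()
    if not cs_active:
        return new
    if ctx_on == "A":
        new.w_A_CS += params.a_A
        new.w_A_CTX += params.a_A
    elif ctx_on == "B":
        new.w_B_CS += params.a_B
        new.w_B_CTX += params.a_B
    return new


def run_rate_phase(
    state: RateModelState,
    params: RateParams,
    stim: RateStimulus,
    duration_ms: float,
    dt_ms: float = 0.1,
    rng: np.random.Generator | None = None,
    plastic: bool = True,
    record_every: int = 10,
):
    """Integrate one phase; weights update at each CS offset.

    Returns (records DataFrame, per-trial peak activities, final state).
    """
    stim.validate()
    params.validate()
    n_steps = int(round(duration_ms / dt_ms))
    offsets = np.sort(np.asarray(stim.cs_times_ms, dtype=float)) + stim.cs_duration_ms
    offset_steps = set(int(round((o - state.t_ms) / dt_ms)) for o in offsets)
    rows = []
    trial_peak_A, trial_peak_B = [], []
    peak_A = peak_B = 0.0
    in_cs = False
    for step in range(n_steps):
        if step in offset_steps:
            if plastic:
                state = update_rate_weights(state, params, cs_active=True, ctx_on=stim.context)
            trial_peak_A.append(peak_A)
            trial_peak_B.append(peak_B)
        cs_now = stim.cs_active(state.t_ms)
        if cs_now and not in_cs:
            peak_A = peak_B = 0.0
        in_cs = cs_now
        state = step_rate_dynamics(state, params, stim, dt_ms, rng)
        if cs_now:
            peak_A = max(peak_A, state.act_A)
            peak_B = max(peak_B, state.act_B)
        if step % record_every == 0:
            rows.append(
                (state.t_ms, state.act_A, state.act_B, state.w_A_CS, state.w_B_CS, state.w_A_CTX, state.w_B_CTX)
            )
    records = pd.DataFrame(
        rows, columns=["time_ms", "act_A", "act_B", "w_A_CS", "w_B_CS", "w_A_CTX", "w_B_CTX"]
    )
    return records, (np.array(trial_peak_A), np.array(trial_peak_B)), state


def default_rate_protocol(n_cond: int = 5, n_ext: int = 6) -> list[RatePhase]:
    """Conditioning in context A followed by extinction in context B."""
    return [
        RatePhase("conditioning", "A", n_cond, plastic=True),
        RatePhase("extinction", "B", n_ext, plastic=True),
    ]


def run_rate_protocol(
    params: RateParams,
    phases: list[RatePhase] | None = None,
    n_repeats: int = 30,
    seed: int = 0,
    dt_ms: float = 0.1,
    iti_ms: float = 500.0,
    cs_duration_ms: float = 50.0,
    cs_amplitude: float = 3.0,
    ctx_amplitude: float = 1.0,
    initial_state: RateModelState | None = None,
) -> pd.DataFrame:
    """Run a multi-phase protocol for several repeats.

    Returns a tidy frame with one row per recorded time point and repeat:
    columns (repeat, phase, time_ms, act_A, act_B, w_A_CS, w_B_CS, w_A_CTX,
    w_B_CTX).  Per-trial peak CS responses are available via
    :func:`rate_trial_summary`.
    """
    if phases is None:
        phases = default_rate_protocol()
    if not phases:
        raise ValueError("protocol must contain at least one phase")
    params.validate()
    frames = []
    for rep in range(n_repeats):
        rng = np.random.default_rng(derive_seed(seed, "rate", rep))
        state = (initial_state or RateModelState()).copy()
        for phase in phases:
            onsets = state.t_ms + 200.0 + iti_ms * np.arange(phase.n_trials)
            stim = RateStimulus(
                cs_times_ms=tuple(onsets),
                cs_duration_ms=cs_duration_ms,
                cs_amplitude=cs_amplitude,
                context=phase.context,
                ctx_amplitude=ctx_amplitude,
            )
            duration = 200.0 + iti_ms * phase.n_trials
            rec, (pk_A, pk_B), state = run_rate_phase(
                state, params, stim, duration, dt_ms, rng, plastic=phase.plastic
            )
            rec.insert(0, "phase", phase.name)
            rec.insert(0, "repeat", rep)
            frames.append(rec)
    return pd.concat(frames, ignore_index=True)


def rate_trial_summary(
    params: RateParams,
    phases: list[RatePhase] | None = None,
    n_repeats: int = 30,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Per-trial peak CS responses, averaged over repeats.

    Convenience wrapper mirroring :func:`run_rate_protocol` but reporting the
    quantity plotted in trial-resolved learning curves: the peak activity of
    each population during each CS pulse.
    """
    if phases is None:
        phases = default_rate_protocol()
    params.validate()
    dt_ms = kwargs.pop("dt_ms", 0.1)
    iti_ms = kwargs.pop("iti_ms", 500.0)
    cs_duration_ms = kwargs.pop("cs_duration_ms", 50.0)
    cs_amplitude = kwargs.pop("cs_amplitude", 3.0)
    ctx_amplitude = kwargs.pop("ctx_amplitude", 1.0)
    if kwargs:
        raise TypeError(f"unknown arguments: {sorted(kwargs)}")
    rows = []
    for rep in range(n_repeats):
        rng = np.random.default_rng(derive_seed(seed, "rate", rep))
        state = RateModelState()
        for phase in phases:
            onsets = state.t_ms + 200.0 + iti_ms * np.arange(phase.n_trials)
            stim = RateStimulus(
                cs_times_ms=tuple(onsets),
                cs_duration_ms=cs_duration_ms,
                cs_amplitude=cs_amplitude,
                context=phase.context,
                ctx_amplitude=ctx_amplitude,
            )
            duration = 200.0 + iti_ms * phase.n_trials
            _, (pk_A, pk_B), state = run_rate_phase(
                state, params, stim, duration, dt_ms, rng, plastic=phase.plastic
            )
            for j, (a, b) in enumerate(zip(pk_A, pk_B)):
                rows.append((rep, phase.name, j + 1, a, b))
    df = pd.DataFrame(rows, columns=["repeat", "phase", "trial", "peak_A", "peak_B"])
    return df.groupby(["phase", "trial"], sort=False)[["peak_A", "peak_B"]].mean().reset_index()
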