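"""Post-hoc quantification of simulated spike records.

Covers per-trial evoked responses, functional classification of excitatory
neurons (fear / extinction / persistent / nonresponsive), recruitment
profiles (abrupt single-neuron switches vs graded population curves), and
synchrony / spectral measures of the population rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "ClassificationResult",
    "SynchronyResult",
    "evoked_response",
    "population_rate",
    "classify_neurons",
    "responsive_mask",
    "distinct_populations",
    "recruitment_profile",
    "synchrony_index",
    "synchrony_and_spectrum",
]

GAMMA_BAND_HZ = (30.0, 80.0)


def evoked_response(
    spike_times_ms: np.ndarray,
    spike_ids: np.ndarray,
    n_neurons: int,
    onsets_ms: np.ndarray,
    window_ms: float = 60.0,
) -> np.ndarray:
    """Per-neuron, per-trial spike counts in ``[onset, onset + window)``.

    Spike times must be sorted (simulation output is).  Returns an
    ``(n_neurons, n_trials)`` integer array; an empty record yields zeros.
    """
    onsets = np.asarray(onsets_ms, dtype=float)
    counts = np.zeros((n_neurons, len(onsets)), dtype=np.int64)
    times = np.asarray(spike_times_ms)
    ids = np.asarray(spike_ids)
    for j, t0 in enumerate(onsets):
        lo, hi = np.searchsorted(times, [t0, t0 + window_ms])
        sel = ids[lo:hi]
        counts[:, j] = np.bincount(sel[sel < n_neurons], minlength=n_neurons)
    return counts


def population_rate(
    spike_times_ms: np.ndarray,
    spike_ids: np.ndarray,
    subset: np.ndarray,
    t0_ms: float,
    t1_ms: float,
    bin_ms: float = 1.0,
):
    """Binned population rate (Hz per neuron) of ``subset`` on [t0, t1)."""
    if t1_ms <= t0_ms:
        raise ValueError("require t1 > t0")
    mask = np.isin(spike_ids, subset)
    times = spike_times_ms[mask]
    times = times[(times >= t0_ms) & (times < t1_ms)]
    n_bins = int(round((t1_ms - t0_ms) / bin_ms))
    counts, edges = np.histogram(times, bins=n_bins, range=(t0_ms, t0_ms + n_bins * bin_ms))
    rate = counts / (len(subset) * bin_ms * 1e-3)
    return edges[:-1], rate


@dataclass
class ClassificationResult:
    """Functional labels for excitatory neurons.

    Labels are exhaustive and mutually exclusive: ``fear`` responds to the CS
    after conditioning only, ``extinction`` after extinction training only,
    ``persistent`` after both, ``nonresponsive`` after neither.  The
    characterisation is purely functional -- it uses the measured responses,
    not the wiring.
    """

    labels: np.ndarray  # (n_exc,) of {fear, extinction, persistent, nonresponsive}
    score_cond: np.ndarray  # responsive-trial fraction post-conditioning
    score_ext: np.ndarray
    criterion: dict = field(default_factory=dict)

    def ids(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    def counts(self) -> dict[str, int]:
        return {lab: int((self.labels == lab).sum()) for lab in
                ("fear", "extinction", "persistent", "nonresponsive")}


def responsive_mask(
    counts: np.ndarray, last_k: int = 3, quorum: int = 2, min_spikes: int = 1
) -> np.ndarray:
    """A neuron is responsive in a phase if it fired >= ``min_spikes`` within
    the response window in at least ``quorum`` of the last ``last_k`` trials."""
    tail = counts[:, -last_k:] if counts.shape[1] >= last_k else counts
    return (tail >= min_spikes).sum(axis=1) >= quorum


def classify_neurons(
    counts_cond: np.ndarray,
    counts_ext: np.ndarray,
    last_k: int = 3,
    quorum: int = 2,
    min_spikes: int = 1,
) -> ClassificationResult:
    """Classify excitatory neurons from post-conditioning and post-extinction
    evoked responses.  Deterministic given the counts and the criterion."""
    if counts_cond.shape[0] != counts_ext.shape[0]:
        raise ValueError("phase count arrays must cover the same neurons")
    resp_c = responsive_mask(counts_cond, last_k, quorum, min_spikes)
    resp_e = responsive_mask(counts_ext, last_k, quorum, min_spikes)
    labels = np.full(counts_cond.shape[0], "nonresponsive", dtype=object)
    labels[resp_c & ~resp_e] = "fear"
    labels[~resp_c & resp_e] = "extinction"
    labels[resp_c & resp_e] = "persistent"
    tail_c = counts_cond[:, -last_k:]
    tail_e = counts_ext[:, -last_k:]
    return ClassificationResult(
        labels=labels.astype("U13"),
        score_cond=(tail_c >= min_spikes).mean(axis=1),
        score_ext=(tail_e >= min_spikes).mean(axis=1),
        criterion={"last_k": last_k, "quorum": quorum, "min_spikes": min_spikes},
    )


def distinct_populations(
    labels: np.ndarray, ext_counts: np.ndarray, factor: float = 2.0, last_k: int = 3
) -> bool:
    """Distinct fear/extinction populations exist at end of extinction when
    extinction-labelled neurons out-respond fear-labelled ones by ``factor``.

    Both groups must be non-empty.  ``ext_counts`` are evoked counts in the
    extinction phase, whose last ``last_k`` trials are averaged.
    """
    fear = np.flatnonzero(labels == "fear")
    ext = np.flatnonzero(labels == "extinction")
    if len(fear) == 0 or len(ext) == 0:
        return False
    tail = ext_counts[:, -last_k:]
    mean_fear = tail[fear].mean()
    mean_ext = tail[ext].mean()
    return mean_ext > factor * max(mean_fear, 1e-12)


def recruitment_profile(counts: np.ndarray, min_spikes: int = 1) -> np.ndarray:
    """Trial at which each neuron switches (persistently) to responding.

    Returns, per neuron, the smallest trial index j (0-based) such that the
    neuron responds on every trial from j to the end; -1 if it never reaches
    a persistent responding state.  The cumulative count of recruited neurons
    over trials is the graded population curve, even though each neuron's
    switch is all-or-none.
    """
    responding = np.asarray(counts) >= min_spikes
    n_neurons, n_trials = responding.shape
    out = np.full(n_neurons, -1, dtype=np.int64)
    # suffix products: responding from j..end
    suffix = np.flip(np.cumprod(np.flip(responding, axis=1), axis=1), axis=1).astype(bool)
    for i in range(n_neurons):
        idx = np.flatnonzero(suffix[i])
        if idx.size:
            out[i] = idx[0]
    return out


@dataclass
class SynchronyResult:
    synchrony_index: float
    frequencies_Hz: np.ndarray
    power: np.ndarray
    peak_frequency_Hz: float
    gamma_power: float
    mean_rate_Hz: float


def _binned_counts(spike_times_ms, spike_ids, subset, t0_ms, t1_ms, bin_ms):
    subset = np.asarray(subset)
    n_bins = int(round((t1_ms - t0_ms) / bin_ms))
    if n_bins < 2:
        raise ValueError("record too short for the requested binning")
    mask = (spike_times_ms >= t0_ms) & (spike_times_ms < t0_ms + n_bins * bin_ms)
    mask &= np.isin(spike_ids, subset)
    times = spike_times_ms[mask]
    ids = spike_ids[mask]
    remap = -np.ones(int(subset.max()) + 2, dtype=np.int64)
    remap[subset] = np.arange(len(subset))
    rows = remap[ids]
    cols = ((times - t0_ms) / bin_ms).astype(np.int64)
    mat = np.zeros((len(subset), n_bins))
    np.add.at(mat, (rows, cols), 1.0)
    return mat


def synchrony_index(
    spike_times_ms: np.ndarray,
    spike_ids: np.ndarray,
    subset: np.ndarray,
    t0_ms: float,
    t1_ms: float,
    bin_ms: float = 2.0,
) -> float:
    """Golomb-Rinzel style synchrony measure on binned spike counts.

    chi^2 = Var(population-averaged signal) / mean(Var(single-neuron signal));
    chi is 1 for perfectly coincident spiking and tends to 0 for independent
    neurons as the population grows.  Returns 0 for a silent record.
    """
    mat = _binned_counts(spike_times_ms, spike_ids, subset, t0_ms, t1_ms, bin_ms)
    pop = mat.mean(axis=0)
    denom = mat.var(axis=1).mean()
    if denom <= 0:
        return 0.0
    chi2 = pop.var() / denom
    return float(np.sqrt(min(max(chi2, 0.0), 1.0)))


def synchrony_and_spectrum(
    spike_times_ms: np.ndarray,
    spike_ids: np.ndarray,
    subset: np.ndarray,
    t0_ms: float,
    t1_ms: float,
    bin_ms: float = 2.0,
    spectrum_bin_ms: float = 1.0,
    segment_ms: float = 1000.0,
) -> SynchronyResult:
    """Synchrony index plus Welch spectrum of the binned population rate.

    The spectrum uses 1 ms bins, 1 s Hann segments with 50% overlap; the peak
    frequency excludes DC.  Requires at least one second of record.
    """
    if len(subset) == 0:
        raise ValueError("subset must be non-empty")
    if t1_ms - t0_ms < 1000.0:
        raise ValueError("need at least 1 s of record for spectral estimates")
    chi = synchrony_index(spike_times_ms, spike_ids, subset, t0_ms, t1_ms, bin_ms)
    _, rate = population_rate(spike_times_ms, spike_ids, subset, t0_ms, t1_ms, spectrum_bin_ms)
    fs = 1000.0 / spectrum_bin_ms
    nperseg = min(int(round(segment_ms / spectrum_bin_ms)), rate.size)
    freqs, psd = signal.welch(rate - rate.mean(), fs=fs, nperseg=nperseg, noverlap=nperseg // 2)
    nonzero = freqs > 0
    peak = float(freqs[nonzero][np.argmax(psd[nonzero])]) if nonzero.any() else 0.0
    in_gamma = (freqs >= GAMMA_BAND_HZ[0]) & (freqs <= GAMMA_BAND_HZ[1])
    df = freqs[1] - freqs[0] if freqs.size > 1 else 0.0
    return SynchronyResult(
        synchrony_index=chi,
        frequencies_Hz=freqs,
        power=psd,
        peak_frequency_Hz=peak,
        gamma_power=float(psd[in_gamma].sum() * df),
        mean_rate_Hz=float(rate.mean()),
    )
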