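"""Evoked responses, classification, recruitment, synchrony and spectra."""

import numpy as np
import pytest

from banetsim import analysis
from banetsim.io import make_fixture


class TestEvokedResponse:
    def test_exact_counts_on_constructed_record(self):
        times = np.array([10.0, 12.0, 55.0, 110.0, 115.0, 118.0, 300.0])
        ids = np.array([0, 1, 0, 2, 2, 0, 1])
        counts = analysis.evoked_response(times, ids, 3, onsets_ms=[10.0, 110.0], window_ms=20.0)
        np.testing.assert_array_equal(counts, [[1, 1], [1, 0], [0, 2]])

    def test_empty_record_gives_zeros(self):
        counts = analysis.evoked_response(np.empty(0), np.empty(0, int), 5, [0.0, 100.0], 50.0)
        assert counts.shape == (5, 2) and counts.sum() == 0


class TestClassification:
    def test_label_assignment_branches(self):
        cond = np.array([[1, 1, 1], [0, 0, 0], [1, 1, 0], [0, 0, 0]])
        ext = np.array([[0, 0, 0], [1, 1, 1], [2, 1, 2], [0, 1, 0]])
        cls = analysis.classify_neurons(cond, ext)
        assert list(cls.labels) == ["fear", "extinction", "persistent", "nonresponsive"]

    def test_quorum_criterion(self):
        # responsive requires >= 1 spike in >= 2 of the last 3 trials
        cond = np.array([[0, 0, 1], [0, 1, 1]])
        ext = np.zeros((2, 3), int)
        cls = analysis.classify_neurons(cond, ext)
        assert list(cls.labels) == ["nonresponsive", "fear"]

    def test_invariant_under_id_relabelling(self):
        rng = np.random.default_rng(0)
        cond = rng.integers(0, 3, (50, 5))
        ext = rng.integers(0, 3, (50, 6))
        perm = rng.permutation(50)
        a = analysis.classify_neurons(cond, ext).labels
        b = analysis.classify_neurons(cond[perm], ext[perm]).labels
        np.testing.assert_array_equal(a[perm], b)

    def test_distinct_populations_criterion(self):
        labels = np.array(["fear"] * 5 + ["extinction"] * 5)
        ext_counts = np.vstack([np.zeros((5, 4)), np.full((5, 4), 2.0)]).astype(int)
        assert analysis.distinct_populations(labels, ext_counts)
        assert not analysis.distinct_populations(labels[:5], ext_counts[:5])  # no ext group


class TestRecruitment:
    def test_known_switch_trials(self):
        counts, switch = make_fixture("binary_recruitment")
        profile = analysis.recruitment_profile(counts)
        assert {i: profile[i] for i in range(3)} == switch

    def test_never_responding_sentinel(self):
        profile = analysis.recruitment_profile(np.zeros((2, 5), int))
        assert np.all(profile == -1)

    def test_population_curve_is_graded_while_neurons_are_binary(self):
        # the average over all-or-none responders equals (recruited count x
        # per-neuron response) / n -- an algebraic identity on the fixture
        counts, switch = make_fixture("binary_recruitment")
        profile = analysis.recruitment_profile(counts)
        pop_curve = counts.mean(axis=0)
        n_trials = counts.shape[1]
        recruited = np.array([(profile <= j)[profile >= 0].sum() for j in range(n_trials)])
        np.testing.assert_allclose(pop_curve, recruited * 2.0 / counts.shape[0])
        assert len(np.unique(pop_curve)) > 2  # graded population curve


class TestSynchrony:
    def test_coincident_spiking_gives_index_near_one(self):
        times, ids, dur = make_fixture("canned_spikes")["sync"]
        chi = analysis.synchrony_index(times, ids, np.arange(20), 0.0, dur)
        assert chi == pytest.approx(1.0, abs=1e-6)

    def test_independent_poisson_gives_small_index(self):
        times, ids, dur = make_fixture("canned_spikes")["poisson"]
        chi = analysis.synchrony_index(times, ids, np.arange(20), 0.0, dur)
        # chi^2 ~ 1/N for independent trains
        assert chi < 3.0 / np.sqrt(20)

    def test_jitter_never_increases_index(self):
        times, ids, dur = make_fixture("canned_spikes")["sync"]
        rng = np.random.default_rng(1)
        jittered = times + rng.normal(0, 5.0, times.size)
        order = np.argsort(jittered)
        chi0 = analysis.synchrony_index(times, ids, np.arange(20), 0.0, dur)
        chi1 = analysis.synchrony_index(jittered[order], ids[order], np.arange(20), 0.0, dur)
        assert chi1 < chi0

    def test_silent_record_index_zero(self):
        assert analysis.synchrony_index(np.empty(0), np.empty(0, int), np.arange(3), 0, 1000.0) == 0.0

    def test_too_short_record_rejected(self):
        with pytest.raises(ValueError):
            analysis.synchrony_and_spectrum(np.empty(0), np.empty(0, int), np.arange(3), 0.0, 500.0)
        with pytest.raises(ValueError):
            analysis.synchrony_and_spectrum(np.empty(0), np.empty(0, int), np.empty(0, int), 0.0, 2000.0)


class TestSpectrum:
    @staticmethod
    def _oscillatory_record(f_hz, duration_ms=10_000.0, n=50, seed=0):
        # sinusoidally rate-modulated Poisson population
        rng = np.random.default_rng(seed)
        dt = 1.0
        t = np.arange(0, duration_ms, dt)
        lam = 0.02 * (1 + 0.8 * np.sin(2 * np.pi * f_hz * t / 1000.0))
        times, ids = [], []
        for i in range(n):
            counts = rng.poisson(lam)
            spike_bins = np.repeat(t, counts)
            times.append(spike_bins)
            ids.append(np.full(spike_bins.size, i))
        times = np.concatenate(times)
        ids = np.concatenate(ids)
        order = np.argsort(times, kind="stable")
        return times[order], ids[order].astype(np.int64)

    def test_peak_frequency_recovers_modulation(self):
        times, ids = self._oscillatory_record(40.0)
        res = analysis.synchrony_and_spectrum(times, ids, np.arange(50), 0.0, 10_000.0)
        assert res.peak_frequency_Hz == pytest.approx(40.0, abs=2.0)
        assert res.gamma_power > 0

    def test_parseval_total_power_matches_variance(self):
        times, ids = self._oscillatory_record(25.0, seed=3)
        res = analysis.synchrony_and_spectrum(times, ids, np.arange(50), 0.0, 10_000.0)
        _, rate = analysis.population_rate(times, ids, np.arange(50), 0.0, 10_000.0, 1.0)
        df = res.frequencies_Hz[1] - res.frequencies_Hz[0]
        total = res.power.sum() * df
        assert total == pytest.approx(rate.var(), rel=0.15)
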