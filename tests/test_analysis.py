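"""Oscillation metrics: filtering, spectra, synchronization and correlation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tcosim import analysis
from tcosim.analysis import (EntrainmentCriteria, LFPTrace, compute_slfp,
                             correlation_index, judge_entrainment,
                             normalized_power, peth, power_spectrum,
                             slfp_peak_times, spike_phase,
                             synchronization_index)

FS = 1000.0  # Hz
T = np.arange(0, 10_000.0, 1000.0 / FS)  # ms


def _tone(freq_hz, amp=1.0, phase=0.0):
    return amp * np.sin(2 * np.pi * freq_hz * T / 1000.0 + phase)


class TestSLFP:
    def test_dc_removed(self):
        lfp = compute_slfp(T, np.full_like(T, -63.0))
        assert np.max(np.abs(lfp.values)) < 1e-6

    def test_in_band_tone_passes_with_unit_gain(self):
        lfp = compute_slfp(T, _tone(9.0))
        mid = slice(len(T) // 4, 3 * len(T) // 4)
        assert np.max(np.abs(lfp.values[mid])) == pytest.approx(1.0, abs=0.05)

    def test_out_of_band_tone_attenuated_20db(self):
        lfp = compute_slfp(T, _tone(120.0))
        mid = slice(len(T) // 4, 3 * len(T) // 4)
        assert np.max(np.abs(lfp.values[mid])) < 0.1

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            compute_slfp(T[:16], _tone(9.0)[:16])

    def test_warmup_cut(self):
        lfp = compute_slfp(T, _tone(9.0), warmup_discard=1000.0)
        assert lfp.times.min() >= 1000.0


class TestPowerSpectrum:
    def test_known_tone_peak(self):
        rng = np.random.default_rng(0)
        lfp = compute_slfp(T, _tone(25.0) + 0.1 * rng.standard_normal(T.size))
        ps = power_spectrum(lfp)
        assert ps.peak_frequency == pytest.approx(25.0, abs=0.5)

    def test_dominant_of_two_tones(self):
        lfp = compute_slfp(T, _tone(9.0, 2.0) + _tone(40.0, 1.0))
        assert power_spectrum(lfp).peak_frequency == pytest.approx(9.0, abs=0.5)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            power_spectrum(LFPTrace(times=np.empty(0), values=np.empty(0)))

    def test_white_noise_peak_unstable_but_power_consistent(self):
        peaks = []
        for seed in (1, 2):
            rng = np.random.default_rng(seed)
            lfp = compute_slfp(T, rng.standard_normal(T.size))
            ps = power_spectrum(lfp)
            band = (ps.frequencies >= 1) & (ps.frequencies <= 80)
            peaks.append(ps.peak_power / ps.power[band].mean())
        # peak-to-mean ratio of featureless noise stays within Monte-Carlo bounds
        assert 0.2 < peaks[0] / peaks[1] < 5.0


class TestSpikePhase:
    peaks = np.array([0.0, 100.0, 200.0])

    def test_phase_examples(self):
        phases, excluded = spike_phase(np.array([0.0, 25.0, 50.0, 150.0]), self.peaks)
        assert excluded == 0
        assert phases == pytest.approx([0.0, 90.0, 180.0, 180.0])

    def test_unbracketed_spikes_excluded(self):
        phases, excluded = spike_phase(np.array([-5.0, 250.0, 50.0]), self.peaks)
        assert excluded == 2
        assert phases.size == 1


class TestSynchronizationIndex:
    def test_identical_phases_unity(self):
        assert synchronization_index([123.4] * 50) == pytest.approx(1.0)

    def test_antiphase_cancels(self):
        assert synchronization_index([0.0, 180.0]) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_phases_near_zero(self):
        rng = np.random.default_rng(11)
        phases = rng.uniform(0, 360, 10_000)
        assert synchronization_index(phases) < 0.05

    def test_empty_undefined(self):
        with pytest.raises(ValueError):
            synchronization_index([])

    @given(st.floats(-360, 360))
    @settings(max_examples=30, deadline=None)
    def test_rotation_invariance(self, shift):
        rng = np.random.default_rng(5)
        phases = rng.uniform(0, 360, 500)
        k0 = synchronization_index(phases)
        k1 = synchronization_index((phases + shift) % 360.0)
        assert k1 == pytest.approx(k0, abs=1e-9)

    def test_matches_complex_resultant_oracle(self):
        """Direct complex-exponential resultant agrees to 1e-12."""
        rng = np.random.default_rng(3)
        phases = rng.uniform(0, 360, 1000)
        oracle = np.abs(np.exp(1j * np.radians(phases)).sum()) / phases.size
        assert synchronization_index(phases) == pytest.approx(oracle, abs=1e-12)


class TestPETH:
    def test_empty_raster_zero_histogram(self):
        h = peth(np.empty(0), 0.0, 100.0, 2.0)
        assert h.sum() == 0 and len(h) == 50

    def test_count_conservation(self):
        rng = np.random.default_rng(0)
        spikes = rng.uniform(0, 1000.0, 100)
        assert peth(spikes, 0.0, 1000.0, 2.0).sum() == 100

    def test_periodic_spikes_bin_pattern(self):
        spikes = np.arange(0.0, 1000.0, 25.0) + 1.0
        h = peth(spikes, 0.0, 1000.0, 2.0)
        occupied = np.nonzero(h)[0]
        assert np.all(np.isin(np.diff(occupied), (12, 13)))


class TestCorrelationIndex:
    def test_identical_is_one(self):
        rng = np.random.default_rng(1)
        h = rng.poisson(3.0, 500).astype(float)
        assert correlation_index(h, h) == pytest.approx(1.0)

    def test_negated_is_minus_one(self):
        rng = np.random.default_rng(2)
        h = rng.poisson(3.0, 500).astype(float)
        neg = 2 * h.mean() - h  # mean-removed form is the exact negation
        assert correlation_index(h, neg) == pytest.approx(-1.0)

    def test_independent_poisson_small(self):
        rng = np.random.default_rng(3)
        a = rng.poisson(3.0, 10_000).astype(float)
        b = rng.poisson(3.0, 10_000).astype(float)
        assert abs(correlation_index(a, b)) < 0.1

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        a = rng.poisson(2.0, 800).astype(float)
        b = np.roll(a, 3) + rng.poisson(1.0, 800)
        assert correlation_index(a, b) == pytest.approx(correlation_index(b, a), abs=1e-12)

    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError):
            correlation_index(np.ones(200), np.arange(200.0))

    def test_matches_direct_quadratic_oracle(self):
        """O(n^2) direct lagged Pearson extremum agrees to 1e-12."""
        rng = np.random.default_rng(6)
        a = rng.poisson(2.0, 400).astype(float)
        b = rng.poisson(2.0, 400).astype(float) + np.roll(a, -5)
        am, bm = a - a.mean(), b - b.mean()
        denom = np.sqrt((am @ am) * (bm @ bm))
        best = 0.0
        for lag in range(-25, 26):
            acc = sum(am[i] * bm[i - lag] for i in range(400) if 0 <= i - lag < 400)
            if abs(acc / denom) > abs(best):
                best = acc / denom
        assert correlation_index(a, b, max_lag_ms=50.0, bin_ms=2.0) == pytest.approx(
            best, abs=1e-12)


class TestEntrainment:
    def _spec(self, f_peak, p_peak):
        return analysis.PowerSpectrum(frequencies=np.array([f_peak]),
                                      power=np.array([p_peak]),
                                      peak_frequency=f_peak, peak_power=p_peak)

    def test_both_criteria_met(self):
        v = judge_entrainment(self._spec(40.3, 1.5), self._spec(35.0, 1.0), 40.0)
        assert v.entrained

    def test_frequency_criterion_fails(self):
        v = judge_entrainment(self._spec(35.0, 1.5), self._spec(35.0, 1.0), 40.0)
        assert not v.entrained

    def test_power_criterion_fails(self):
        v = judge_entrainment(self._spec(40.0, 0.8), self._spec(35.0, 1.0), 40.0)
        assert not v.entrained

    def test_monotone_in_power_ratio(self):
        base = self._spec(35.0, 1.0)
        verdicts = [judge_entrainment(self._spec(40.0, p), base, 40.0).entrained
                    for p in (0.5, 0.9, 1.1, 3.0)]
        assert verdicts == sorted(verdicts)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            normalized_power(self._spec(40.0, 1.0), self._spec(35.0, 0.0))

    def test_normalized_power_identity_and_scaling(self):
        rng = np.random.default_rng(0)
        sig = _tone(30.0) + 0.05 * rng.standard_normal(T.size)
        ps1 = power_spectrum(compute_slfp(T, sig))
        ps2 = power_spectrum(compute_slfp(T, 2.0 * sig))
        assert normalized_power(ps1, ps1) == pytest.approx(1.0)
        # power convention: doubling the amplitude quadruples the ratio
        assert normalized_power(ps2, ps1) == pytest.approx(4.0, rel=0.05)

    def test_invalid_tolerance(self):
        with pytest.raises(ValueError):
            EntrainmentCriteria(frequency_tolerance=0.0)


def test_peak_picking_on_synthetic_oscillation():
    lfp = compute_slfp(T, _tone(10.0))
    peaks = slfp_peak_times(lfp, dominant_freq=10.0)
    gaps = np.diff(peaks)
    assert np.allclose(gaps, 100.0, atol=2.0)


class TestPopulationCI:
    def test_aggregates_mean_over_pairs(self):
        """Thalamic CI = mean over the six population pairs."""
        rng = np.random.default_rng(8)

        class FakeResult:
            warmup_discard = 0.0
            duration = 2000.0

            def __init__(self):
                common = np.sort(rng.uniform(0, 2000.0, 400))
                self._trains = {
                    pop: np.sort(np.concatenate([
                        common + rng.normal(0, 1.0, common.size),
                        rng.uniform(0, 2000.0, 100)]))
                    for pop in ("HTC", "RTC", "IN", "RE")
                }

            def spike_times(self, pop):
                return self._trains[pop]

        res = FakeResult()
        agg = analysis.population_ci(res, analysis.THALAMIC_CI_PAIRS)
        singles = [analysis.correlation_index(
            analysis.peth(res.spike_times(a), 0.0, 2000.0, 2.0),
            analysis.peth(res.spike_times(b), 0.0, 2000.0, 2.0))
            for a, b in analysis.THALAMIC_CI_PAIRS]
        assert agg == pytest.approx(np.mean(singles), abs=1e-12)
        assert agg > 0.3  # strongly co-modulated by construction
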