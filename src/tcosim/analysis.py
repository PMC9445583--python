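"""Oscillation metrics: sLFP, spectrum, synchronization and correlation indices.

The simulated local field potential (sLFP) is the population-mean membrane
potential band-passed to 0.5-80 Hz (zero-phase FIR).  The network rhythm is
the spectral-peak frequency of the sLFP; spike synchrony is quantified by
the resultant length of spike phases measured between successive positive
sLFP peaks; pairwise population coupling by the extremum of the normalized
cross-correlation of mean-removed 2-ms peri-event time histograms; and
entrainment by |f_s - f_d| < 1 Hz together with a stimulated/baseline
spectral-peak ratio above 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy import signal

__all__ = [
    "LFPTrace",
    "PowerSpectrum",
    "EntrainmentCriteria",
    "SynchronyResult",
    "compute_slfp",
    "power_spectrum",
    "slfp_peak_times",
    "spike_phase",
    "synchronization_index",
    "peth",
    "correlation_index",
    "normalized_power",
    "judge_entrainment",
    "thalamic_slfp",
    "cortical_slfp",
]

DEFAULT_BAND = (0.5, 80.0)

#: population pairs entering the aggregate correlation indices
THALAMIC_CI_PAIRS = (("HTC", "RTC"), ("HTC", "IN"), ("HTC", "RE"),
                     ("RTC", "IN"), ("RTC", "RE"), ("IN", "RE"))
CORTEX_CI_PAIRS = (("PY", "FS"),)
THALAMOCORTICAL_CI_PAIRS = (("PY", "RTC"), ("PY", "RE"), ("FS", "RTC"))


@dataclass
class LFPTrace:
    times: np.ndarray      # ms
    values: np.ndarray     # mV, band-passed
    source: str = "thalamus"
    band: Tuple[float, float] = DEFAULT_BAND

    @property
    def fs_hz(self) -> float:
        dt = self.times[1] - self.times[0]
        return 1000.0 / dt


@dataclass
class PowerSpectrum:
    frequencies: np.ndarray
    power: np.ndarray
    peak_frequency: float
    peak_power: float


@dataclass
class EntrainmentCriteria:
    frequency_tolerance: float = 1.0   # Hz
    power_ratio_threshold: float = 1.0  # sigma

    def __post_init__(self):
        if self.frequency_tolerance <= 0:
            raise ValueError("frequency tolerance must be > 0")


@dataclass
class SynchronyResult:
    phases: np.ndarray     # degrees in [0, 360)
    index: float           # resultant length in [0, 1]
    excluded: int = 0      # spikes outside the bracketed peak region


def _design_bandpass(fs_hz: float, band=DEFAULT_BAND, n_samples: int = None) -> np.ndarray:
    """Linear-phase FIR band-pass (window method, Hamming).

    The order follows the low band edge (about 1.5 cycles of it), capped at a
    third of the trace so the forward-backward (zero-phase) application stays
    well conditioned on short records.
    """
    lo, hi = band
    nyq = fs_hz / 2.0
    hi = min(hi, 0.99 * nyq)
    numtaps = int(1.5 * fs_hz / lo) | 1
    if n_samples is not None:
        numtaps = min(numtaps, (n_samples // 3) | 1)
    if numtaps < 11:
        raise ValueError("trace shorter than the filter transient")
    return signal.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs_hz)


def compute_slfp(times: np.ndarray, mean_voltage: np.ndarray,
                 band=DEFAULT_BAND, source: str = "thalamus",
                 warmup_discard: float = 0.0) -> LFPTrace:
    """Band-pass the population-mean voltage into an sLFP trace.

    Traces sampled above 2 kHz are first decimated to about 1 kHz (the band
    ends at 80 Hz, so this loses nothing).  ``warmup_discard`` (ms) is cut
    after filtering so edge transients of the zero-phase filter fall inside
    the discarded segment.
    """
    times = np.asarray(times, float)
    v = np.asarray(mean_voltage, float)
    if len(v) < 32:
        raise ValueError("trace too short to filter")
    dt = times[1] - times[0]
    fs = 1000.0 / dt
    if fs < 200.0:
        raise ValueError("sLFP requires sampling at >= 200 Hz")
    if fs > 2000.0:
        factor = int(round(fs / 1000.0))
        v = signal.decimate(v, factor, zero_phase=True)
        times = times[::factor][: len(v)]
        fs /= factor
    taps = _design_bandpass(fs, band, n_samples=len(v))
    padlen = min(len(v) - 1, 3 * (len(taps) - 1))
    filtered = signal.filtfilt(taps, [1.0], v - v.mean(), padtype="even", padlen=padlen)
    keep = times >= warmup_discard
    return LFPTrace(times=times[keep], values=filtered[keep], source=source, band=band)


def thalamic_slfp(result, band=DEFAULT_BAND) -> LFPTrace:
    """sLFP over all TCs: mean voltage of HTC and RTC cells, size-weighted."""
    sizes = result._pop_sizes
    n = sizes["HTC"] + sizes["RTC"]
    v = (result.mean_voltage["HTC"] * sizes["HTC"]
         + result.mean_voltage["RTC"] * sizes["RTC"]) / n
    return compute_slfp(result.times, v, band, "thalamus", result.warmup_discard)


def cortical_slfp(result, band=DEFAULT_BAND) -> LFPTrace:
    """sLFP over all cortical cells (PY and FS), size-weighted."""
    sizes = result._pop_sizes
    n = sizes["PY"] + sizes["FS"]
    v = (result.mean_voltage["PY"] * sizes["PY"]
         + result.mean_voltage["FS"] * sizes["FS"]) / n
    return compute_slfp(result.times, v, band, "cortex", result.warmup_discard)


def power_spectrum(lfp: LFPTrace, eval_band: Tuple[float, float] = (1.0, 80.0)) -> PowerSpectrum:
    """Averaged power spectrum of the sLFP; peak searched inside ``eval_band``.

    Uses Welch's method (Hann window, 2-s segments, 50% overlap) so the
    dominant-frequency readout is stable against single-periodogram noise;
    the frequency resolution is 0.5 Hz.
    """
    v = np.asarray(lfp.values, float)
    if v.size == 0:
        raise ValueError("empty trace")
    dt_s = (lfp.times[1] - lfp.times[0]) / 1000.0
    if v.size * dt_s < 2.0:
        raise ValueError("need >= 2 s of data for <= 0.5 Hz resolution")
    fs = 1.0 / dt_s
    nperseg = min(int(round(2.0 * fs)), v.size)
    freqs, spec = signal.welch(v, fs=fs, window="hann", nperseg=nperseg,
                               noverlap=nperseg // 2, detrend="constant")
    lo, hi = eval_band
    mask = (freqs >= lo) & (freqs <= hi)
    k = np.argmax(spec[mask])
    f_peak = float(freqs[mask][k])
    p_peak = float(spec[mask][k])
    return PowerSpectrum(frequencies=freqs, power=spec,
                         peak_frequency=f_peak, peak_power=p_peak)


def slfp_peak_times(lfp: LFPTrace, dominant_freq: Optional[float] = None) -> np.ndarray:
    """Positive local maxima of the sLFP, separated by >= half the dominant period."""
    if dominant_freq is None:
        dominant_freq = power_spectrum(lfp).peak_frequency
    dt = lfp.times[1] - lfp.times[0]
    min_dist = max(int(0.5 * 1000.0 / dominant_freq / dt), 1)
    idx, _ = signal.find_peaks(lfp.values, height=0.0, distance=min_dist)
    return lfp.times[idx]


def spike_phase(spike_times: np.ndarray, peak_times: np.ndarray) -> Tuple[np.ndarray, int]:
    """Phase of each spike between the bracketing positive sLFP peaks, degrees.

    Spikes before the first or after the last peak cannot be bracketed and
    are excluded; the second return value counts them.
    """
    spikes = np.asarray(spike_times, float)
    peaks = np.sort(np.asarray(peak_times, float))
    if peaks.size < 2:
        return np.empty(0), int(spikes.size)
    idx = np.searchsorted(peaks, spikes, side="right")
    ok = (idx >= 1) & (idx < peaks.size)
    j = idx[ok]
    last = peaks[j - 1]
    nxt = peaks[j]
    phi = (spikes[ok] - last) / (nxt - last) * 360.0
    return np.mod(phi, 360.0), int(np.sum(~ok))


def synchronization_index(phases: Iterable[float]) -> float:
    """Resultant length k = |sum e^{i phi}| / N of the spike phases."""
    phi = np.radians(np.asarray(list(phases), float))
    n = phi.size
    if n == 0:
        raise ValueError("synchronization index undefined for zero spikes")
    return float(np.hypot(np.sin(phi).sum(), np.cos(phi).sum()) / n)


def spike_synchrony(result, lfp: LFPTrace, pops=("HTC", "RTC")) -> SynchronyResult:
    """SI of pooled TC spikes against the thalamic sLFP peaks."""
    peaks = slfp_peak_times(lfp)
    t0 = result.warmup_discard
    pooled = np.concatenate([result.spike_times(p) for p in pops])
    pooled = pooled[pooled >= t0]
    phases, excluded = spike_phase(pooled, peaks)
    if phases.size == 0:
        return SynchronyResult(phases=phases, index=np.nan, excluded=excluded)
    return SynchronyResult(phases=phases, index=synchronization_index(phases),
                           excluded=excluded)


def peth(spike_times: np.ndarray, t_start: float, t_stop: float,
         bin_ms: float = 2.0) -> np.ndarray:
    """Spike counts in consecutive ``bin_ms`` bins over [t_start, t_stop)."""
    if bin_ms <= 0:
        raise ValueError("bin width must be > 0")
    edges = np.arange(t_start, t_stop + bin_ms / 2, bin_ms)
    counts, _ = np.histogram(np.asarray(spike_times, float), bins=edges)
    return counts.astype(float)


def correlation_index(peth_a: np.ndarray, peth_b: np.ndarray,
                      max_lag_ms: float = 50.0, bin_ms: float = 2.0) -> float:
    """Signed extremum of the normalized cross-correlation of mean-removed PETHs.

    The Pearson-normalized cross-correlogram is scanned over lags within
    +-``max_lag_ms``; the value with the largest magnitude is returned with
    its sign, so mutually inhibitory pairs yield negative indices.
    """
    a = np.asarray(peth_a, float)
    b = np.asarray(peth_b, float)
    if a.shape != b.shape:
        raise ValueError("PETHs must have equal length")
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        raise ValueError("correlation index undefined for a zero-variance PETH")
    max_lag = int(round(max_lag_ms / bin_ms))
    cc = signal.correlate(a, b, mode="full") / denom
    center = len(a) - 1
    window = cc[center - max_lag: center + max_lag + 1]
    k = np.argmax(np.abs(window))
    return float(window[k])


def population_ci(result, pairs: Sequence[Tuple[str, str]],
                  bin_ms: float = 2.0) -> float:
    """Mean CI over population pairs (PETHs pooled over each population)."""
    t0, t1 = result.warmup_discard, result.duration
    vals = []
    for pa, pb in pairs:
        ha = peth(result.spike_times(pa), t0, t1, bin_ms)
        hb = peth(result.spike_times(pb), t0, t1, bin_ms)
        vals.append(correlation_index(ha, hb, bin_ms=bin_ms))
    return float(np.mean(vals))


def normalized_power(spectrum: PowerSpectrum, baseline: PowerSpectrum) -> float:
    """P_max / P_0: stimulated spectral peak over the unstimulated peak."""
    if baseline.peak_power <= 0:
        raise ValueError("baseline spectral peak is zero; ratio undefined")
    return spectrum.peak_power / baseline.peak_power


@dataclass
class EntrainmentVerdict:
    entrained: bool
    dominant_frequency: float
    power_ratio: float
    stimulus_frequency: float
    diagnostics: Dict[str, float] = field(default_factory=dict)


def judge_entrainment(spectrum: PowerSpectrum, baseline: PowerSpectrum,
                      f_s: float,
                      criteria: Optional[EntrainmentCriteria] = None,
                      diagnostics: Optional[Dict[str, float]] = None) -> EntrainmentVerdict:
    """Entrainment iff |f_s - f_d| < tolerance and P_max/P_0 > sigma."""
    criteria = criteria or EntrainmentCriteria()
    ratio = normalized_power(spectrum, baseline)
    f_d = spectrum.peak_frequency
    ok = (abs(f_s - f_d) < criteria.frequency_tolerance
          and ratio > criteria.power_ratio_threshold)
    return EntrainmentVerdict(
        entrained=bool(ok), dominant_frequency=f_d, power_ratio=ratio,
        stimulus_frequency=f_s, diagnostics=diagnostics or {})
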