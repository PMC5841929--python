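"""Sharp-wave-ripple detection with MUA gating and event metrics.

Candidate events are periods where the smoothed ripple-band (80-250 Hz)
envelope exceeds the rest-epoch mean by 3 SD for more than 30 ms; event
edges extend to where the envelope returns to the mean. Candidates not
coincident with a multi-unit activity (MUA) burst — detected on the
summed, smoothed instantaneous population rate with the same
mean + 3 SD / >30 ms rule — are discarded as potential artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d

from .core import DataError, LFPSignal, SpikeTrain, interval_overlap


@dataclass
class RippleDetectionParams:
    band: tuple = (80.0, 250.0)
    fir_order: int = 69                 # Kaiser-window FIR, zero-phase
    kaiser_beta: float = 6.0
    env_smooth_window_ms: float = 50.0  # Gaussian window; SD = window / 6
    threshold_sd: float = 3.0
    min_dur_ms: float = 30.0
    mua_bin_ms: float = 1.0
    mua_smooth_sd_ms: float = 5.0
    mua_gate: bool = True

    def __post_init__(self):
        if self.threshold_sd <= 0 or self.min_dur_ms <= 0:
            raise DataError("threshold_sd and min_dur_ms must be positive")

    @property
    def env_smooth_sd_ms(self) -> float:
        return self.env_smooth_window_ms / 6.0


@dataclass
class RippleEvent:
    t_start: float
    t_end: float
    t_peak: float
    amplitude_sd: float        # peak envelope in SDs above the mean
    amplitude_raw: float       # peak envelope in signal units
    core_duration_ms: float    # above-threshold span
    peak_freq_hz: float = float("nan")

    @property
    def duration_ms(self) -> float:
        """Extended (mean-to-mean) span in ms."""
        return (self.t_end - self.t_start) * 1000.0


@dataclass
class RippleUnitStats:
    unit_id: str
    spikes_per_ripple: float
    participation: float       # fraction of events with >=1 spike
    n_events: int


def ripple_bandpass(lfp: LFPSignal, params: RippleDetectionParams) -> np.ndarray:
    """Zero-phase Kaiser-window FIR band-pass of the rest-epoch LFP."""
    numtaps = params.fir_order + 1
    if len(lfp.samples) < 10 * numtaps:
        raise DataError("epoch too short for the ripple filter")
    taps = signal.firwin(numtaps, list(params.band), pass_zero=False,
                         window=("kaiser", params.kaiser_beta), fs=lfp.fs_hz)
    return signal.filtfilt(taps, [1.0], lfp.samples)


def ripple_envelope(lfp: LFPSignal, params: RippleDetectionParams = None):
    """Smoothed ripple-band envelope with its rest-epoch mean and SD.

    Band-pass filter, magnitude of the analytic (Hilbert) signal, Gaussian
    smoothing with a 50 ms window (SD = window/6). Returns
    ``(envelope, filtered, mean, sd)``.
    """
    params = params or RippleDetectionParams()
    filt = ripple_bandpass(lfp, params)
    env = np.abs(signal.hilbert(filt))
    sd_samples = params.env_smooth_sd_ms / 1000.0 * lfp.fs_hz
    env = gaussian_filter1d(env, sd_samples, mode="reflect")
    return env, filt, float(env.mean()), float(env.std())


def _threshold_events(x: np.ndarray, t0: float, fs: float, mean: float,
                      sd: float, threshold_sd: float, min_dur_ms: float,
                      min_rule: str = "span"):
    """Threshold detection shared by the LFP-envelope and MUA paths.

    An event is a maximal above-mean excursion (so its edges sit at the
    return-to-mean crossings) that reaches mean + threshold_sd * SD. The
    ``min_dur_ms`` test applies to the mean-to-mean span (``"span"``, the
    LFP-envelope rule) or to the above-threshold core (``"core"``, used
    for MUA, whose near-zero mean makes the excursion span of a single
    stray spike meaningless). Events at a higher threshold are always a
    subset of those at a lower one.
    """
    thr = mean + threshold_sd * sd
    above_mean = x > mean
    above_thr = x > thr
    min_samples = min_dur_ms / 1000.0 * fs

    events = []
    n = len(x)
    i = 0
    while i < n:
        if above_mean[i]:
            j = i
            while j + 1 < n and above_mean[j + 1]:
                j += 1
            core = int(np.count_nonzero(above_thr[i:j + 1]))
            measure = core if min_rule == "core" else (j - i + 1)
            if core > 0 and measure > min_samples:
                k = i + int(np.argmax(x[i:j + 1]))
                events.append(RippleEvent(
                    t_start=t0 + i / fs, t_end=t0 + (j + 1) / fs,
                    t_peak=t0 + k / fs,
                    amplitude_sd=(float(x[k]) - mean) / sd if sd > 0 else float("inf"),
                    amplitude_raw=float(x[k]),
                    core_duration_ms=core / fs * 1000.0))
            i = j + 1
        else:
            i += 1
    return events


def detect_ripples(envelope: np.ndarray, lfp: LFPSignal,
                   params: RippleDetectionParams = None,
                   mean: float = None, sd: float = None) -> list:
    """Candidate ripple events from a precomputed envelope."""
    params = params or RippleDetectionParams()
    if mean is None:
        mean = float(envelope.mean())
    if sd is None:
        sd = float(envelope.std())
    return _threshold_events(envelope, lfp.t0, lfp.fs_hz, mean, sd,
                             params.threshold_sd, params.min_dur_ms)


def mua_rate(spikes: list, t0: float, t1: float,
             params: RippleDetectionParams = None):
    """Summed instantaneous population rate (Hz), 1 ms bins, smoothed."""
    params = params or RippleDetectionParams()
    bin_s = params.mua_bin_ms / 1000.0
    edges = np.arange(t0, t1 + bin_s, bin_s)
    counts = np.zeros(len(edges) - 1)
    for tr in spikes:
        sel = tr.t[(tr.t >= t0) & (tr.t < t1)]
        counts += np.histogram(sel, bins=edges)[0]
    rate = counts / bin_s
    rate = gaussian_filter1d(rate, params.mua_smooth_sd_ms / params.mua_bin_ms,
                             mode="reflect")
    fs = 1.0 / bin_s
    return rate, fs


def detect_mua_bursts(spikes: list, t0: float, t1: float,
                      params: RippleDetectionParams = None) -> list:
    """Population firing bursts by the same mean + 3 SD / >30 ms rule."""
    params = params or RippleDetectionParams()
    rate, fs = mua_rate(spikes, t0, t1, params)
    return _threshold_events(rate, t0, fs, float(rate.mean()),
                             float(rate.std()), params.threshold_sd,
                             params.min_dur_ms, min_rule="core")


def mua_gate(events: list, spikes: list, t0: float, t1: float,
             params: RippleDetectionParams = None):
    """Keep only candidate events coincident with an MUA burst."""
    bursts = detect_mua_bursts(spikes, t0, t1, params)
    gated = [ev for ev in events
             if any(interval_overlap(ev.t_start, ev.t_end,
                                     b.t_start, b.t_end) > 0 for b in bursts)]
    return gated, bursts


def ripple_frequency(event: RippleEvent, filtered: np.ndarray,
                     lfp: LFPSignal, params: RippleDetectionParams = None,
                     n_tapers: int = 3, nw: float = 2.0,
                     nfft: int = 4096) -> float:
    """Peak ripple-band frequency via multitaper on the Hanning-windowed,
    band-pass-filtered event waveform."""
    params = params or RippleDetectionParams()
    i0 = max(0, int((event.t_start - lfp.t0) * lfp.fs_hz))
    i1 = min(len(filtered), int(np.ceil((event.t_end - lfp.t0) * lfp.fs_hz)))
    seg = filtered[i0:i1]
    if len(seg) < 8:
        return float("nan")
    seg = seg * np.hanning(len(seg))
    tapers = signal.windows.dpss(len(seg), nw, Kmax=n_tapers)
    nfft = max(nfft, len(seg))
    freqs = np.fft.rfftfreq(nfft, 1.0 / lfp.fs_hz)
    spec = np.zeros(len(freqs))
    for tap in tapers:
        spec += np.abs(np.fft.rfft(seg * tap, n=nfft)) ** 2
    band = (freqs >= params.band[0]) & (freqs <= params.band[1])
    return float(freqs[band][np.argmax(spec[band])])


def detect_ripples_full(lfp: LFPSignal, spikes: list,
                        params: RippleDetectionParams = None):
    """Envelope -> candidates -> MUA gate -> per-event peak frequency."""
    params = params or RippleDetectionParams()
    env, filt, mean, sd = ripple_envelope(lfp, params)
    events = detect_ripples(env, lfp, params, mean, sd)
    t0, t1 = lfp.t0, lfp.t0 + lfp.duration_s
    if params.mua_gate:
        events, _ = mua_gate(events, spikes, t0, t1, params)
    for ev in events:
        ev.peak_freq_hz = ripple_frequency(ev, filt, lfp, params)
    return events


@dataclass
class RippleMetrics:
    rate_per_min: float
    mean_iri_s: float
    mean_amplitude_sd: float
    mean_duration_ms: float
    mean_peak_freq_hz: float
    n_events: int


def ripple_metrics(events: list, epoch_duration_s: float) -> RippleMetrics:
    """Per-session (per-animal) ripple summary."""
    if epoch_duration_s <= 0:
        raise DataError("epoch duration must be positive")
    n = len(events)
    rate = n / (epoch_duration_s / 60.0)
    if n == 0:
        return RippleMetrics(rate, float("nan"), float("nan"),
                             float("nan"), float("nan"), 0)
    starts = np.array([ev.t_start for ev in events])
    iri = float(np.mean(np.diff(starts))) if n >= 2 else float("nan")
    freqs = [ev.peak_freq_hz for ev in events if np.isfinite(ev.peak_freq_hz)]
    return RippleMetrics(
        rate, iri,
        float(np.mean([ev.amplitude_sd for ev in events])),
        float(np.mean([ev.duration_ms for ev in events])),
        float(np.mean(freqs)) if freqs else float("nan"), n)


def ripple_unit_stats(events: list, train: SpikeTrain) -> RippleUnitStats:
    """Spikes per ripple and participation of one unit in the events."""
    if not events:
        return RippleUnitStats(train.unit_id, float("nan"), float("nan"), 0)
    counts = [int(np.count_nonzero((train.t >= ev.t_start)
                                   & (train.t < ev.t_end))) for ev in events]
    counts = np.array(counts)
    return RippleUnitStats(train.unit_id, float(counts.mean()),
                           float(np.mean(counts > 0)), len(events))


def participation_histogram(stats: list, bin_width: float = 0.05):
    """Population histogram of unit participation in 5% bins."""
    edges = np.arange(0, 1 + bin_width, bin_width)
    vals = np.array([s.participation for s in stats if np.isfinite(s.participation)])
    counts, _ = np.histogram(vals, bins=edges)
    frac = counts / counts.sum() if counts.sum() else counts.astype(float)
    return frac, edges


def threshold_sweep(lfp: LFPSignal, spikes: list,
                    thresholds=(2.0, 3.0, 6.0),
                    params: RippleDetectionParams = None) -> dict:
    """Repeat detection and unit stats at each envelope threshold."""
    params = params or RippleDetectionParams()
    env, filt, mean, sd = ripple_envelope(lfp, params)
    t0, t1 = lfp.t0, lfp.t0 + lfp.duration_s
    out = {}
    for th in thresholds:
        p = replace(params, threshold_sd=th)
        events = detect_ripples(env, lfp, p, mean, sd)
        if p.mua_gate:
            events, _ = mua_gate(events, spikes, t0, t1, p)
        for ev in events:
            ev.peak_freq_hz = ripple_frequency(ev, filt, lfp, p)
        out[th] = {
            "events": events,
            "metrics": ripple_metrics(events, lfp.duration_s),
            "unit_stats": [ripple_unit_stats(events, tr) for tr in spikes],
        }
    return out


def detect_events_mua_only(spikes: list, t0: float, t1: float,
                           params: RippleDetectionParams = None) -> list:
    """Events from multi-unit spiking alone (no LFP)."""
    if not spikes:
        return []
    return detect_mua_bursts(spikes, t0, t1, params)
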