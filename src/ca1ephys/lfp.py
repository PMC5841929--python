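"""LFP conditioning, Welch PSD, theta phase, and spike phase locking.

The wide-band signal is anti-alias filtered and decimated (32556 Hz / 20
= 1627.8 Hz in the reference acquisition). Power spectra use Welch's
averaged modified periodogram restricted to running periods and are
normalised by the mean power in the delta (1-3 Hz) band so curves are
comparable across animals/electrodes.

Theta phase is anchored at the filtered-trace extrema — peaks are 0 deg,
troughs 180 deg — with linear interpolation between anchors, which is
insensitive to theta wave asymmetry. Spike phase statistics use a 36-bin
(10 deg) firing-probability histogram, the circular mean and resultant
length, the Rayleigh test, and a KL-divergence modulation index
normalised to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .circstats import kl_from_uniform, rayleigh_test, resultant_vector
from .core import ConfigurationError, DataError, LFPSignal, SpikeTrain, VelocityTrace

THETA_BAND = (6.0, 12.0)
DELTA_BAND = (1.0, 3.0)
PHASE_BIN_DEG = 10.0
PHASE_SPEED_MIN_CM_S = 6.0


@dataclass
class PSDResult:
    freq_hz: np.ndarray
    power_norm: np.ndarray      # mean over the delta band equals 1
    n_segments: int


@dataclass
class ThetaPhaseSeries:
    """Interpolated theta phase per LFP sample plus extrema anchors."""

    t: np.ndarray
    phase_deg: np.ndarray       # [0, 360)
    anchor_t: np.ndarray        # alternating peak/trough times
    anchor_phase: np.ndarray    # cumulative phase (deg) at anchors

    def phase_at(self, times: np.ndarray) -> np.ndarray:
        """Phase (deg, [0, 360)) at arbitrary times by anchor interpolation."""
        cum = np.interp(np.asarray(times, dtype=float),
                        self.anchor_t, self.anchor_phase)
        return cum % 360.0


@dataclass
class PhaseLockStats:
    unit_id: str
    hist: np.ndarray            # 36-bin firing probability, sums to 1
    preferred_phase_deg: float
    resultant_r: float
    rayleigh_p: float
    kl_div: float               # nats
    mod_index: float            # kl / ln(n_bins), in [0, 1]
    significant: bool
    n_spikes: int
    low_n: bool


def _fir_bandpass(band, fs: float, numtaps: int = None) -> np.ndarray:
    """Symmetric FIR band-pass; default length gives >=40 dB stopband a
    half-band away from the edges after forward-backward filtering."""
    lo, hi = band
    if numtaps is None:
        # transition width ~= half the lower edge
        numtaps = int(np.ceil(3.3 * fs / (lo / 2))) | 1
    return signal.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs)


def downsample_lfp(raw: LFPSignal, factor: int = 20) -> LFPSignal:
    """Anti-alias low-pass at the target Nyquist, then decimate.

    The low-pass cut-off is half the target sampling frequency and the
    filter is applied zero-phase before taking every ``factor``-th sample.
    """
    if factor < 1:
        raise ConfigurationError("decimation factor must be >= 1")
    if factor == 1:
        return LFPSignal(raw.samples.copy(), raw.fs_hz, raw.channel_id, raw.t0)
    out_fs = raw.fs_hz / factor
    sos = signal.butter(8, out_fs / 2, btype="low", fs=raw.fs_hz, output="sos")
    filtered = signal.sosfiltfilt(sos, raw.samples)
    return LFPSignal(filtered[::factor], out_fs, raw.channel_id, raw.t0)


def welch_psd(lfp: LFPSignal, vel: VelocityTrace = None, win: int = 2048,
              overlap: float = 0.5, nfft: int = 4096,
              vmin: float = 2.0) -> PSDResult:
    """Velocity-gated Welch PSD normalised to unit mean delta power.

    Hann-windowed modified periodograms of ``win``-sample segments with
    the given fractional overlap are averaged over segments whose midpoint
    speed is at least ``vmin`` (all segments when ``vel`` is None), then
    the curve is divided by its own mean power over 1-3 Hz.
    """
    x = lfp.samples
    step = int(win * (1 - overlap))
    if len(x) < win:
        raise DataError("signal shorter than one Welch window")
    window = signal.get_window("hann", win)
    scale = 1.0 / (lfp.fs_hz * (window ** 2).sum())
    freqs = np.fft.rfftfreq(nfft, 1.0 / lfp.fs_hz)

    acc = np.zeros(len(freqs))
    n_seg = 0
    for start in range(0, len(x) - win + 1, step):
        mid_t = lfp.t0 + (start + win / 2) / lfp.fs_hz
        if vel is not None and vel.at(np.array([mid_t]))[0] < vmin:
            continue
        seg = x[start:start + win]
        seg = (seg - seg.mean()) * window
        spec = np.abs(np.fft.rfft(seg, n=nfft)) ** 2 * scale
        spec[1:-1] *= 2.0   # one-sided
        acc += spec
        n_seg += 1
    if n_seg == 0:
        raise DataError("no Welch segments pass the velocity gate")
    psd = acc / n_seg
    delta = (freqs >= DELTA_BAND[0]) & (freqs <= DELTA_BAND[1])
    ref = psd[delta].mean()
    if ref <= 0:
        raise DataError("zero delta-band power; cannot normalise")
    return PSDResult(freqs, psd / ref, n_seg)


def band_mean_power(psd: PSDResult, lo_hz: float, hi_hz: float) -> float:
    """Mean normalised power in [lo_hz, hi_hz]; the unit-level statistic
    for across-group per-band PSD comparisons."""
    m = (psd.freq_hz >= lo_hz) & (psd.freq_hz <= hi_hz)
    if not m.any():
        raise DataError("band outside the frequency grid")
    return float(psd.power_norm[m].mean())


def theta_phase(lfp: LFPSignal, band=THETA_BAND) -> ThetaPhaseSeries:
    """Waveform-anchored theta phase.

    The trace is band-pass filtered zero-phase in ``band``; peaks are
    assigned 0 deg and troughs 180 deg, and phase advances linearly in
    time between consecutive extrema.
    """
    taps = _fir_bandpass(band, lfp.fs_hz)
    if len(lfp.samples) <= 3 * len(taps):
        raise DataError("signal too short for the theta filter")
    filt = signal.filtfilt(taps, [1.0], lfp.samples)

    min_dist = int(lfp.fs_hz / (2 * band[1]))   # > quarter period apart
    peaks, _ = signal.find_peaks(filt, distance=min_dist)
    troughs, _ = signal.find_peaks(-filt, distance=min_dist)
    if len(peaks) == 0 or len(troughs) == 0:
        raise DataError("no theta extrema found (flat signal?)")

    # merge into a strictly alternating anchor sequence, keeping the more
    # extreme candidate when two of the same type are adjacent
    idx = np.concatenate([peaks, troughs])
    kind = np.concatenate([np.zeros(len(peaks), int), np.ones(len(troughs), int)])
    order = np.argsort(idx)
    idx, kind = idx[order], kind[order]
    keep_idx, keep_kind = [], []
    for i, k in zip(idx, kind):
        if keep_kind and keep_kind[-1] == k:
            better = abs(filt[i]) > abs(filt[keep_idx[-1]])
            if better:
                keep_idx[-1] = i
        else:
            keep_idx.append(i)
            keep_kind.append(k)
    idx = np.array(keep_idx)
    kind = np.array(keep_kind)

    # cumulative phase: each anchor advances 180 deg; offset so peaks = 0 (mod 360)
    anchor_phase = 180.0 * np.arange(len(idx))
    if kind[0] == 1:            # first anchor is a trough
        anchor_phase += 180.0
    anchor_t = lfp.t0 + idx / lfp.fs_hz
    t = lfp.t
    phase = np.interp(t, anchor_t, anchor_phase) % 360.0
    return ThetaPhaseSeries(t, phase, anchor_t, anchor_phase)


def spike_phase_stats(spikes: SpikeTrain, phase: ThetaPhaseSeries,
                      vel: VelocityTrace = None,
                      vmin: float = PHASE_SPEED_MIN_CM_S,
                      alpha: float = 0.05,
                      n_bins: int = 36) -> PhaseLockStats:
    """Theta phase-locking summary of one unit.

    Spikes are kept only while running (speed >= ``vmin``); their phases
    come from anchor interpolation at the spike times. The histogram is a
    firing *probability* per 10-degree bin. ``mod_index`` is the KL
    divergence from uniform divided by ln(n_bins), so 0 means uniform and
    1 means all spikes in one bin.
    """
    t = spikes.t
    if vel is not None:
        t = t[vel.at(t) >= vmin]
    if len(t) == 0:
        raise DataError("no spikes above the speed threshold")
    ph_deg = phase.phase_at(t)
    ph_rad = np.deg2rad(ph_deg)

    edges = np.linspace(0, 360, n_bins + 1)
    counts, _ = np.histogram(ph_deg, bins=edges)
    hist = counts / counts.sum()

    r, mu = resultant_vector(ph_rad)
    p = rayleigh_test(ph_rad)
    kl = kl_from_uniform(hist)
    mi = kl / np.log(n_bins)
    return PhaseLockStats(spikes.unit_id, hist, float(np.rad2deg(mu)), r, p,
                          kl, mi, p < alpha, len(t), len(t) < 10)
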