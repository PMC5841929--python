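"""Complex-spike index, burst detection, and burst/ISI statistics.

Pyramidal cells emit complex-spike bursts: runs of 2+ spikes at short
inter-spike intervals whose amplitudes attenuate through the burst. The
complex spike index (CSI) scores that attenuation; bursts themselves are
chains of consecutive ISIs within a 10 ms window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DataError, SpikeTrain

CSI_REFRACTORY_MS = 3.0    # ISIs below this always count against the CSI
CSI_MAX_ISI_MS = 15.0      # pairs beyond this are not burst-related
BURST_WINDOW_MS = 10.0


@dataclass
class Burst:
    t_start: float
    t_end: float
    n_spikes: int
    spike_idx: np.ndarray  # indices into the unit's spike train

    @property
    def duration_ms(self) -> float:
        return (self.t_end - self.t_start) * 1000.0


@dataclass
class BurstStats:
    bursts_per_min: float
    mean_interburst_s: float
    mean_duration_ms: float
    pct_spikes_in_burst: float
    spikes_per_burst: float
    n_bursts: int
    n_spikes: int


def complex_spike_index(t: np.ndarray, amp: np.ndarray):
    """CSI of a spike train from consecutive-pair amplitude attenuation.

    For each consecutive spike pair with ISI <= 15 ms: the pair counts as
    ``pos`` when the ISI is in [3, 15] ms and the second spike is smaller
    (a complex burst signature); it counts as ``neg`` when the amplitude
    increases or the ISI violates the 3 ms refractory bound. Pairs with
    ISI > 15 ms are ignored. The index is 100 * (pos - neg) normalised by
    the eligible pair count, bounded in [-100, 100].

    Returns ``(csi, pos, neg)``.
    """
    t = np.asarray(t, dtype=float)
    amp = np.asarray(amp, dtype=float)
    if len(t) < 2:
        raise DataError("CSI undefined for <2 spikes")
    isi_ms = np.diff(t) * 1000.0
    damp = np.diff(amp)
    eligible = isi_ms <= CSI_MAX_ISI_MS
    pos = int(np.count_nonzero(eligible & (isi_ms >= CSI_REFRACTORY_MS)
                               & (damp < 0)))
    neg = int(np.count_nonzero(eligible)) - pos
    csi = 100.0 * (pos - neg) / max(1, pos + neg)
    return csi, pos, neg


def csi_for_train(train: SpikeTrain):
    """CSI on the unit's reference channel (largest mean amplitude)."""
    ch = train.reference_channel()
    return complex_spike_index(train.t, train.amp[:, ch])


def detect_bursts(t: np.ndarray, window_ms: float = BURST_WINDOW_MS) -> list:
    """Greedy transitive chaining: consecutive ISIs <= window join a burst;
    maximal chains of length >= 2 are emitted."""
    t = np.asarray(t, dtype=float)
    bursts: list[Burst] = []
    if len(t) < 2:
        return bursts
    w = window_ms / 1000.0
    start = 0
    for i in range(1, len(t) + 1):
        if i == len(t) or t[i] - t[i - 1] > w:
            if i - start >= 2:
                bursts.append(Burst(float(t[start]), float(t[i - 1]),
                                    i - start, np.arange(start, i)))
            start = i
    return bursts


def burst_statistics(bursts: list, t: np.ndarray,
                     epoch_duration_s: float) -> BurstStats:
    """Per-unit burst summary over an epoch of known duration."""
    if epoch_duration_s <= 0:
        raise DataError("epoch duration must be positive")
    t = np.asarray(t, dtype=float)
    n = len(bursts)
    rate = n / (epoch_duration_s / 60.0)
    if n == 0:
        return BurstStats(rate, float("nan"), float("nan"), 0.0,
                          float("nan"), 0, len(t))
    starts = np.array([b.t_start for b in bursts])
    ibi = float(np.mean(np.diff(starts))) if n >= 2 else float("nan")
    dur = float(np.mean([b.duration_ms for b in bursts]))
    n_in = int(sum(b.n_spikes for b in bursts))
    pct = 100.0 * n_in / len(t) if len(t) else 0.0
    spb = n_in / n
    return BurstStats(rate, ibi, dur, pct, spb, n, len(t))


def isi_histogram_mode(t: np.ndarray, lo_ms: float = 1.0, hi_ms: float = 1e4,
                       bins_per_decade: int = 50):
    """ISI histogram on log-spaced bins and its modal ISI.

    Bins span 1 ms to 10 s at 50 bins per decade; the mode is the
    (geometric) centre of the maximal-count bin — the most probable ISI.

    Returns ``(isi_mode_ms, counts, bin_edges_ms)``.
    """
    t = np.asarray(t, dtype=float)
    if len(t) < 2:
        raise DataError("ISI mode undefined for <2 spikes")
    isi_ms = np.diff(t) * 1000.0
    n_decades = np.log10(hi_ms / lo_ms)
    edges = np.logspace(np.log10(lo_ms), np.log10(hi_ms),
                        int(round(n_decades * bins_per_decade)) + 1)
    counts, _ = np.histogram(isi_ms, bins=edges)
    k = int(np.argmax(counts))
    mode = float(np.sqrt(edges[k] * edges[k + 1]))
    return mode, counts, edges
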