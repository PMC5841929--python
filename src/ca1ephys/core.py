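"""Shared in-memory containers for a recording session.

All times are seconds from session start (64-bit floats); epochs are
half-open ``[start, end)`` intervals. Positions are in cm, LFP samples in
arbitrary (or microvolt) units at a stated sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ConfigurationError(ValueError):
    """Invalid analysis or simulation configuration."""


class DataError(ValueError):
    """Input data violates a schema or precondition."""


@dataclass
class PositionTrace:
    """Tracked animal position samples.

    ``valid`` flags samples that are usable as recorded; artifact repair
    (``behavior.clean_positions``) clears the flag on replaced samples.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.t.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.t) == len(self.x) == len(self.y) == len(self.valid)):
            raise DataError("position arrays must have equal length")
        if len(self.t) >= 2 and np.any(np.diff(self.t) <= 0):
            raise DataError("position timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def fs_hz(self) -> float:
        """Nominal sampling rate (median inverse interval)."""
        return 1.0 / float(np.median(np.diff(self.t)))


@dataclass
class VelocityTrace:
    """Instantaneous speed (cm/s) aligned to position sample times."""

    t: np.ndarray
    speed: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        if len(self.t) != len(self.speed):
            raise DataError("velocity arrays must have equal length")

    def at(self, times: np.ndarray) -> np.ndarray:
        """Speed linearly interpolated at arbitrary times."""
        return np.interp(np.asarray(times, dtype=float), self.t, self.speed)


@dataclass
class Lap:
    """One complete end-to-end traversal of the linear track."""

    direction: str  # "left" | "right"
    t_start: float
    t_end: float
    x_start: float
    x_end: float


@dataclass
class SpikeTrain:
    """One sorted unit: event times plus per-spike amplitudes and features.

    ``amp`` is (n_spikes, n_channels) peak amplitude per recording channel;
    ``features`` is (n_spikes, n_features); ``width_us`` is the mean spike
    width in microseconds (an input from the sorting stage).
    """

    unit_id: str
    t: np.ndarray
    amp: np.ndarray = None  # type: ignore[assignment]
    features: np.ndarray = None  # type: ignore[assignment]
    width_us: float = float("nan")

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if len(self.t) >= 2 and np.any(np.diff(self.t) < 0):
            raise DataError(f"unit {self.unit_id}: spike times must be sorted")
        if self.amp is None:
            self.amp = np.zeros((len(self.t), 1))
        else:
            self.amp = np.atleast_2d(np.asarray(self.amp, dtype=float))
            if self.amp.shape[0] != len(self.t):
                self.amp = self.amp.T
        if self.features is None:
            self.features = np.zeros((len(self.t), 0))
        else:
            self.features = np.asarray(self.features, dtype=float)
        if len(self.amp) != len(self.t) or len(self.features) != len(self.t):
            raise DataError(f"unit {self.unit_id}: amp/features length mismatch")

    @property
    def n_spikes(self) -> int:
        return len(self.t)

    def reference_channel(self) -> int:
        """Channel with the largest mean amplitude (CSI reference)."""
        if self.amp.size == 0:
            return 0
        return int(np.argmax(self.amp.mean(axis=0)))

    def in_interval(self, t0: float, t1: float) -> "SpikeTrain":
        """Restrict to spikes in the half-open interval [t0, t1)."""
        m = (self.t >= t0) & (self.t < t1)
        return SpikeTrain(self.unit_id, self.t[m], self.amp[m],
                          self.features[m], self.width_us)


@dataclass
class LFPSignal:
    """Continuous local field potential channel."""

    samples: np.ndarray
    fs_hz: float
    channel_id: str = "lfp0"
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs_hz <= 0:
            raise DataError("fs_hz must be positive")

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) / self.fs_hz

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs_hz

    def segment(self, t0: float, t1: float) -> "LFPSignal":
        """Samples in [t0, t1), keeping the global time base."""
        i0 = max(0, int(np.ceil((t0 - self.t0) * self.fs_hz)))
        i1 = min(len(self.samples), int(np.ceil((t1 - self.t0) * self.fs_hz)))
        return LFPSignal(self.samples[i0:i1], self.fs_hz, self.channel_id,
                         self.t0 + i0 / self.fs_hz)


@dataclass
class Epochs:
    """Disjoint labeled session intervals (run vs rest), half-open."""

    run: list = field(default_factory=list)    # list[(t0, t1)]
    rest: list = field(default_factory=list)   # list[(t0, t1)]

    def all_intervals(self):
        return [("run", a, b) for a, b in self.run] + \
               [("rest", a, b) for a, b in self.rest]

    def total(self, kind: str) -> float:
        return float(sum(b - a for a, b in getattr(self, kind)))


def interval_overlap(a0: float, a1: float, b0: float, b1: float) -> float:
    """Length of intersection of [a0,a1) and [b0,b1)."""
    return max(0.0, min(a1, b1) - max(a0, b0))


def match_intervals(detected, truth):
    """Greedy one-to-one matching of detected to ground-truth intervals.

    Two intervals match if they overlap at all. Returns
    (n_matched, recall, precision).
    """
    used = np.zeros(len(truth), dtype=bool)
    n_match = 0
    for d0, d1 in detected:
        for j, (t0, t1) in enumerate(truth):
            if not used[j] and interval_overlap(d0, d1, t0, t1) > 0:
                used[j] = True
                n_match += 1
                break
    recall = n_match / len(truth) if truth else float("nan")
    precision = n_match / len(detected) if detected else float("nan")
    return n_match, recall, precision
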