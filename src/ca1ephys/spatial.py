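"""Rate maps, directional rate curves, place fields and spatial metrics.

The linear track is collapsed to its principal axis and binned at 1 cm.
Occupancy and spike maps are restricted to samples where running speed
is at least 2 cm/s; unvisited bins are masked throughout. The firing
rate map is spike count over occupancy time per bin, smoothed with a
1-bin-SD Gaussian kernel (divide-then-smooth by default; the
smooth-then-divide variant is selectable).

Spatial metrics follow the standard definitions: Skaggs spatial
information SI = sum_i p_i * lam_i * log2(lam_i / lam_bar) in bits/s,
sparsity = 1 - (sum p_i lam_i)^2 / (sum p_i lam_i^2), and directionality
index DI = |FR_lm - FR_rm| / (FR_lm + FR_rm) on direction-mean rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .behavior import lap_mask
from .core import DataError, PositionTrace, SpikeTrain, VelocityTrace

RUN_SPEED_MIN_CM_S = 2.0
FIELD_THRESHOLD_FRAC = 0.20      # field bins exceed 20% of the peak rate
MIN_FIELD_BINS = 6
MIN_MEAN_RATE_HZ = 0.2
MIN_PEAK_RATE_HZ = 1.0
MIDDLE_TRACK_FRAC = 0.80         # DI restricted to fields in middle 80%


@dataclass
class RateMap:
    """Occupancy-normalised firing over 1 cm track bins."""

    rate: np.ndarray            # Hz per bin (smoothed), NaN where unvisited
    occ_time_s: np.ndarray      # raw occupancy seconds per bin
    p: np.ndarray               # occupancy probability, sums to 1 over visited
    visited: np.ndarray         # bool per bin
    bin_size_cm: float = 1.0
    smoothing_sd_bins: float = 1.0
    spike_count: np.ndarray = None  # type: ignore[assignment]

    @property
    def mean_rate(self) -> float:
        """Occupancy-weighted mean rate (Hz) over visited bins."""
        v = self.visited
        return float(np.sum(self.p[v] * self.rate[v]))

    @property
    def peak_rate(self) -> float:
        v = self.visited
        return float(np.nanmax(self.rate[v])) if v.any() else 0.0

    @property
    def n_bins(self) -> int:
        return len(self.rate)


@dataclass
class RateCurve:
    """Directional 1D firing-rate curve over track bins."""

    direction: str
    rate: np.ndarray
    occ_time_s: np.ndarray
    visited: np.ndarray
    mean_rate: float            # direction-mean firing rate (FR_lm / FR_rm)


@dataclass
class PlaceField:
    bin_set: np.ndarray         # contiguous bin indices, ascending
    peak_bin: int
    peak_rate: float
    infield_rate: float = float("nan")
    outfield_rate: float = float("nan")

    @property
    def size_bins(self) -> int:
        return len(self.bin_set)


@dataclass
class SpatialMetrics:
    unit_id: str
    peak_rate: float
    mean_rate: float
    infield_rate: float
    outfield_rate: float
    field_size_bins: int
    si_bits_per_s: float
    sparsity: float
    snr: float
    di: float
    is_place_cell: bool
    field: PlaceField = field(default=None, repr=False)


def _masked_smooth(values: np.ndarray, mask: np.ndarray, sd_bins: float):
    """Normalised Gaussian convolution over a masked 1D array."""
    if sd_bins <= 0:
        out = values.copy()
        out[~mask] = np.nan
        return out
    v = np.where(mask, values, 0.0)
    num = gaussian_filter1d(v, sd_bins, mode="reflect")
    den = gaussian_filter1d(mask.astype(float), sd_bins, mode="reflect")
    out = np.full_like(values, np.nan, dtype=float)
    ok = den > 1e-12
    out[ok] = num[ok] / den[ok]
    out[~mask] = np.nan
    return out


def compute_rate_map(spikes: SpikeTrain, lin_pos: np.ndarray,
                     pos: PositionTrace, vel: VelocityTrace,
                     track_length_cm: float, bin_cm: float = 1.0,
                     smooth_sd_bins: float = 1.0,
                     vmin: float = RUN_SPEED_MIN_CM_S,
                     smooth_mode: str = "divide_then_smooth",
                     time_mask: np.ndarray = None) -> RateMap:
    """Occupancy-normalised rate map over track bins.

    ``lin_pos`` is the 1D track coordinate per position sample. Occupancy
    and spikes are restricted to samples/times with speed >= ``vmin`` (and
    optionally a boolean per-sample ``time_mask``, e.g. laps of one
    direction). Smoothing is applied after division by default; the
    smooth-then-divide variant smooths spike and occupancy maps separately
    before dividing.
    """
    n_bins = int(np.ceil(track_length_cm / bin_cm))
    dt = np.median(np.diff(pos.t))
    keep = vel.at(pos.t) >= vmin
    if time_mask is not None:
        keep &= time_mask
    bins = np.clip((lin_pos / bin_cm).astype(int), 0, n_bins - 1)
    occ = np.bincount(bins[keep], minlength=n_bins) * dt

    sp_keep = vel.at(spikes.t) >= vmin
    if time_mask is not None:
        sp_keep &= np.interp(spikes.t, pos.t, time_mask.astype(float)) > 0.5
    sp_lin = np.interp(spikes.t[sp_keep], pos.t, lin_pos)
    sp_bins = np.clip((sp_lin / bin_cm).astype(int), 0, n_bins - 1)
    count = np.bincount(sp_bins, minlength=n_bins).astype(float)

    visited = occ > 0
    if not visited.any():
        raise DataError("zero total occupancy above the speed threshold")

    if smooth_mode == "divide_then_smooth":
        raw = np.full(n_bins, np.nan)
        raw[visited] = count[visited] / occ[visited]
        rate = _masked_smooth(raw, visited, smooth_sd_bins)
    elif smooth_mode == "smooth_then_divide":
        s_count = _masked_smooth(count, visited, smooth_sd_bins)
        s_occ = _masked_smooth(occ, visited, smooth_sd_bins)
        rate = np.full(n_bins, np.nan)
        ok = visited & (s_occ > 0)
        rate[ok] = s_count[ok] / s_occ[ok]
    else:
        raise DataError(f"unknown smooth_mode {smooth_mode!r}")

    p = np.zeros(n_bins)
    p[visited] = occ[visited] / occ[visited].sum()
    return RateMap(rate=rate, occ_time_s=occ, p=p, visited=visited,
                   bin_size_cm=bin_cm, smoothing_sd_bins=smooth_sd_bins,
                   spike_count=count)


def compute_rate_curves(spikes: SpikeTrain, lin_pos: np.ndarray,
                        pos: PositionTrace, vel: VelocityTrace, laps,
                        track_length_cm: float, bin_cm: float = 1.0,
                        smooth_sd_bins: float = 1.0,
                        vmin: float = RUN_SPEED_MIN_CM_S):
    """Left and right directional rate curves from lap-restricted data."""
    curves = {}
    for direction in ("left", "right"):
        mask = lap_mask(pos.t, laps, direction)
        if not mask.any():
            curves[direction] = RateCurve(direction,
                                          np.full(int(np.ceil(track_length_cm / bin_cm)), np.nan),
                                          np.zeros(int(np.ceil(track_length_cm / bin_cm))),
                                          np.zeros(int(np.ceil(track_length_cm / bin_cm)), bool),
                                          float("nan"))
            continue
        m = compute_rate_map(spikes, lin_pos, pos, vel, track_length_cm,
                             bin_cm, smooth_sd_bins, vmin, time_mask=mask)
        # direction-mean rate: spikes in these laps / time in these laps
        sp_mask = lap_mask(spikes.t, laps, direction) & (vel.at(spikes.t) >= vmin)
        t_total = float(m.occ_time_s.sum())
        fr = float(np.count_nonzero(sp_mask)) / t_total if t_total > 0 else float("nan")
        curves[direction] = RateCurve(direction, m.rate, m.occ_time_s,
                                      m.visited, fr)
    return curves["left"], curves["right"]


def detect_place_fields(rmap: RateMap):
    """Contiguous-bin place fields around the rate-map peak.

    The main field is the maximal contiguous bin set containing the global
    peak with rate above 20% of the peak. Secondary fields are the other
    contiguous supra-threshold components. Returns
    ``(fields, main_field)``; ``main_field`` is None for a silent map.
    """
    v = rmap.visited
    if not v.any() or np.nanmax(rmap.rate[v]) <= 0:
        return [], None
    rate = np.where(v, rmap.rate, -np.inf)
    peak_bin = int(np.nanargmax(rate))
    peak = float(rate[peak_bin])
    above = np.where(v, rmap.rate > FIELD_THRESHOLD_FRAC * peak, False)

    fields = []
    main = None
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            bin_set = np.arange(i, j + 1)
            f = PlaceField(bin_set, int(bin_set[np.argmax(rmap.rate[bin_set])]),
                           float(np.max(rmap.rate[bin_set])))
            fields.append(f)
            if i <= peak_bin <= j:
                main = f
            i = j + 1
        else:
            i += 1
    return fields, main


def in_out_field_rates(spikes: SpikeTrain, lin_pos: np.ndarray,
                       pos: PositionTrace, vel: VelocityTrace,
                       rmap: RateMap, field: PlaceField,
                       vmin: float = RUN_SPEED_MIN_CM_S):
    """Raw in-field and out-field mean rates (spikes / occupancy time)."""
    dt = np.median(np.diff(pos.t))
    keep = vel.at(pos.t) >= vmin
    bins = np.clip((lin_pos / rmap.bin_size_cm).astype(int), 0, rmap.n_bins - 1)
    infield_bins = np.zeros(rmap.n_bins, dtype=bool)
    infield_bins[field.bin_set] = True
    t_in = float(np.count_nonzero(keep & infield_bins[bins])) * dt
    t_out = float(np.count_nonzero(keep & ~infield_bins[bins] & rmap.visited[bins])) * dt

    sp_keep = vel.at(spikes.t) >= vmin
    sp_lin = np.interp(spikes.t[sp_keep], pos.t, lin_pos)
    sp_bins = np.clip((sp_lin / rmap.bin_size_cm).astype(int), 0, rmap.n_bins - 1)
    n_in = int(np.count_nonzero(infield_bins[sp_bins]))
    n_out = int(np.count_nonzero(~infield_bins[sp_bins]))
    r_in = n_in / t_in if t_in > 0 else float("nan")
    r_out = n_out / t_out if t_out > 0 else 0.0
    return r_in, r_out


def spatial_information(rmap: RateMap) -> float:
    """Skaggs spatial information rate in bits per second."""
    v = rmap.visited
    lam = rmap.rate[v]
    p = rmap.p[v]
    lam_bar = float(np.sum(p * lam))
    if lam_bar <= 0:
        return 0.0
    pos_mask = lam > 0
    return float(np.sum(p[pos_mask] * lam[pos_mask]
                        * np.log2(lam[pos_mask] / lam_bar)))


def sparsity(rmap: RateMap) -> float:
    """Rate-map sparsity: 0 for a uniform map, ->1 for a single-bin map."""
    v = rmap.visited
    lam = rmap.rate[v]
    p = rmap.p[v]
    num = float(np.sum(p * lam)) ** 2
    den = float(np.sum(p * lam ** 2))
    if den <= 0:
        raise DataError("sparsity undefined for a silent map")
    return 1.0 - num / den


def directionality_index(fr_lm: float, fr_rm: float) -> float:
    """|FR_lm - FR_rm| / (FR_lm + FR_rm) on direction-mean rates."""
    s = fr_lm + fr_rm
    if s <= 0 or not np.isfinite(s):
        raise DataError("DI undefined when both direction means are zero")
    return abs((fr_lm - fr_rm) / s)


def signal_to_noise(infield_rate: float, outfield_rate: float) -> float:
    """log2 in-field/out-field rate ratio; positive iff in-field exceeds
    out-field. Out-field rate 0 with in-field spikes gives +inf."""
    if infield_rate <= 0:
        return float("-inf")
    if outfield_rate <= 0:
        return float("inf")
    return float(np.log2(infield_rate / outfield_rate))


def mean_run_rate(spikes: SpikeTrain, vel: VelocityTrace,
                  vmin: float = RUN_SPEED_MIN_CM_S) -> float:
    """Run-epoch mean rate: spikes during speed >= vmin over that time."""
    dt = np.median(np.diff(vel.t))
    run_time = float(np.count_nonzero(vel.speed >= vmin)) * dt
    if run_time <= 0:
        raise DataError("no run time above the speed threshold")
    n = int(np.count_nonzero(vel.at(spikes.t) >= vmin))
    return n / run_time


def unit_spatial_metrics(unit_id: str, spikes: SpikeTrain,
                         lin_pos: np.ndarray, pos: PositionTrace,
                         vel: VelocityTrace, laps,
                         track_length_cm: float,
                         bin_cm: float = 1.0) -> SpatialMetrics:
    """All single-cell spatial metrics for one unit.

    A place cell requires main-field size >= 6 bins, mean rate > 0.2 Hz,
    peak rate > 1.0 Hz and positive SNR. DI is computed only when the main
    field's peak bin lies in the middle 80% of the track (NaN otherwise).
    """
    rmap = compute_rate_map(spikes, lin_pos, pos, vel, track_length_cm, bin_cm)
    fields, main = detect_place_fields(rmap)
    mean_rate = mean_run_rate(spikes, vel)
    peak = rmap.peak_rate

    if main is None:
        return SpatialMetrics(unit_id, peak, mean_rate, float("nan"),
                              float("nan"), 0, spatial_information(rmap),
                              float("nan"), float("nan"), float("nan"),
                              False, None)

    r_in, r_out = in_out_field_rates(spikes, lin_pos, pos, vel, rmap, main)
    main.infield_rate, main.outfield_rate = r_in, r_out
    snr = signal_to_noise(r_in, r_out)
    is_pc = (main.size_bins >= MIN_FIELD_BINS and mean_rate > MIN_MEAN_RATE_HZ
             and peak > MIN_PEAK_RATE_HZ and snr > 0)

    di = float("nan")
    lo = (1 - MIDDLE_TRACK_FRAC) / 2 * track_length_cm
    hi = track_length_cm - lo
    peak_cm = (main.peak_bin + 0.5) * bin_cm
    if is_pc and lo <= peak_cm <= hi:
        left, right = compute_rate_curves(spikes, lin_pos, pos, vel, laps,
                                          track_length_cm, bin_cm)
        if np.isfinite(left.mean_rate) and np.isfinite(right.mean_rate) \
                and left.mean_rate + right.mean_rate > 0:
            di = directionality_index(left.mean_rate, right.mean_rate)

    sp = sparsity(rmap) if rmap.mean_rate > 0 else float("nan")
    return SpatialMetrics(unit_id, peak, mean_rate, r_in, r_out,
                          main.size_bins, spatial_information(rmap), sp,
                          snr, di, bool(is_pc), main)
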