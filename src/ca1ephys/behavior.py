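"""Position cleaning, smoothing, velocity, and lap segmentation.

Tracking artifacts (diode occlusions) appear as single-frame jumps far
faster than a mouse can move; they are flagged and linearly interpolated.
Positions are then smoothed with a Gaussian kernel (SD in seconds) and
speed is computed from frame-to-frame displacement and smoothed with a
Gaussian kernel whose SD is expressed in samples.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .core import ConfigurationError, DataError, Lap, PositionTrace, VelocityTrace

#: implied speed above which a sample is treated as a tracking artifact,
#: far above mouse running speed
JUMP_THRESHOLD_CM_S = 150.0


def clean_positions(raw: PositionTrace,
                    jump_cm_s: float = JUMP_THRESHOLD_CM_S):
    """Remove tracking artifacts by interpolating over implausible jumps.

    A sample whose arrival requires instantaneous speed above ``jump_cm_s``
    is flagged invalid and replaced by linear interpolation from the
    nearest valid neighbours. Samples already flagged invalid on input are
    repaired the same way.

    Returns ``(cleaned, n_repaired)``.
    """
    if len(raw) < 2:
        raise DataError("need at least 2 position samples")
    t, x, y = raw.t.copy(), raw.x.copy(), raw.y.copy()
    valid = raw.valid.copy()
    # forward scan from the last accepted sample so a single outlier does
    # not invalidate the (plausible) sample that follows it
    last = None
    for i in range(len(t)):
        if not valid[i]:
            continue
        if last is None:
            last = i
            continue
        dt = t[i] - t[last]
        speed = float(np.hypot(x[i] - x[last], y[i] - y[last])) / dt
        if speed > jump_cm_s:
            valid[i] = False
        else:
            last = i
    if not valid.any():
        raise DataError("all position samples invalid")
    n_repaired = int((~valid).sum())
    good = np.flatnonzero(valid)
    x = np.interp(t, t[good], x[good])
    y = np.interp(t, t[good], y[good])
    cleaned = PositionTrace(t, x, y, np.ones_like(valid))
    return cleaned, n_repaired


def _check_uniform(t: np.ndarray) -> float:
    dt = np.diff(t)
    if len(dt) == 0:
        raise DataError("need at least 2 samples")
    if np.any(dt <= 0):
        raise DataError("duplicate or non-increasing timestamps")
    if np.ptp(dt) > 1e-3 * np.median(dt):   # tolerate clock/format jitter
        raise DataError("non-uniform sampling; resample first")
    return float(np.median(dt))


def smooth_positions(p: PositionTrace, sd_s: float = 0.05) -> PositionTrace:
    """Gaussian-smooth x and y with kernel SD ``sd_s`` seconds.

    Reflective edge handling; requires uniform sampling. ``sd_s = 0``
    returns the input unchanged.
    """
    dt = _check_uniform(p.t)
    if sd_s < 0:
        raise ConfigurationError("sd_s must be nonnegative")
    if sd_s == 0:
        return PositionTrace(p.t.copy(), p.x.copy(), p.y.copy(), p.valid.copy())
    sd_samples = sd_s / dt
    x = gaussian_filter1d(p.x, sd_samples, mode="reflect")
    y = gaussian_filter1d(p.y, sd_samples, mode="reflect")
    return PositionTrace(p.t.copy(), x, y, p.valid.copy())


def compute_velocity(p: PositionTrace, smooth_sd_samples: float = 2.5) -> VelocityTrace:
    """Speed from Euclidean per-step displacement, Gaussian smoothed.

    The raw step speed is assigned to the midpoint sample and interpolated
    back onto the sample times, then smoothed with a Gaussian kernel of SD
    ``smooth_sd_samples`` samples.
    """
    if len(p) < 2:
        raise DataError("need at least 2 samples")
    dt = np.diff(p.t)
    if np.any(dt <= 0):
        raise DataError("duplicate timestamps")
    step_speed = np.hypot(np.diff(p.x), np.diff(p.y)) / dt
    mid_t = 0.5 * (p.t[:-1] + p.t[1:])
    speed = np.interp(p.t, mid_t, step_speed)
    if smooth_sd_samples > 0:
        speed = gaussian_filter1d(speed, smooth_sd_samples, mode="nearest")
    return VelocityTrace(p.t.copy(), np.maximum(speed, 0.0))


def project_to_track(p: PositionTrace) -> np.ndarray:
    """Project (x, y) onto the principal track axis; returns 1D position (cm).

    The axis is the first principal component of the cleaned positions;
    the projection is shifted so its minimum is 0 and oriented so it
    correlates positively with x.
    """
    xy = np.column_stack([p.x, p.y])
    center = xy.mean(axis=0)
    u, s, vt = np.linalg.svd(xy - center, full_matrices=False)
    axis = vt[0]
    if axis[0] < 0:
        axis = -axis
    proj = (xy - center) @ axis
    return proj - proj.min()


def detect_laps(p: PositionTrace, track_length_cm: float = None,
                end_zone_frac: float = 0.10) -> list:
    """Segment a back-and-forth trajectory into directional laps.

    A lap is a traversal from one end zone (outer ``end_zone_frac`` of the
    track) to the other. Brief mid-track reversals that do not re-enter the
    starting end zone stay inside the lap; excursions that return to the
    start zone are discarded. Direction is ``"right"`` for increasing track
    coordinate, ``"left"`` for decreasing.
    """
    lin = project_to_track(p)
    if track_length_cm is None:
        track_length_cm = float(lin.max())
    lo = end_zone_frac * track_length_cm
    hi = (1.0 - end_zone_frac) * track_length_cm

    laps: list[Lap] = []
    state = None          # end zone we last occupied: "low" | "high"
    t_leave = None        # time of last sample inside that end zone
    i_leave = None
    for i in range(len(lin)):
        zone = "low" if lin[i] <= lo else ("high" if lin[i] >= hi else None)
        if zone is None:
            continue
        if state is None:
            state, t_leave, i_leave = zone, p.t[i], i
        elif zone == state:
            t_leave, i_leave = p.t[i], i   # dithered back: restart the lap
        else:
            laps.append(Lap(
                direction="right" if zone == "high" else "left",
                t_start=float(t_leave), t_end=float(p.t[i]),
                x_start=float(lin[i_leave]), x_end=float(lin[i]),
            ))
            state, t_leave, i_leave = zone, p.t[i], i
    return laps


def lap_mask(t: np.ndarray, laps, direction: str = None) -> np.ndarray:
    """Boolean mask of times falling inside laps (optionally one direction)."""
    t = np.asarray(t, dtype=float)
    m = np.zeros(t.shape, dtype=bool)
    for lap in laps:
        if direction is None or lap.direction == direction:
            m |= (t >= lap.t_start) & (t < lap.t_end)
    return m
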