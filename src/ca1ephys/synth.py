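"""Ground-truth-annotated synthetic linear-track sessions.

The generator emulates the statistical structure the downstream analyses
assume — nothing biophysical. A session is a run epoch (back-and-forth
laps on a 170 x 10 cm track at ~15 cm/s, tracked at 30 Hz) followed by a
rest epoch. Each unit fires as an inhomogeneous Poisson process (1 kHz
Bernoulli thinning) whose rate is a Gaussian spatial tuning times a
direction gain times a von Mises theta modulation; emitted events expand
into complex bursts with attenuating amplitudes. The LFP is 1/f^beta
noise plus a theta sinusoid during running; during rest,
Hanning-windowed ripple-band wave packets are injected together with
coincident multi-unit bursts. Every latent quantity (tunings, burst
membership, spike theta phase, injected ripple intervals) is recorded as
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from .core import ConfigurationError, Epochs, LFPSignal, PositionTrace, SpikeTrain
from .ripples import RippleDetectionParams, ripple_envelope

POS_FS_HZ = 30.0          # diode-tracking behavioural sampling rate
REFRACTORY_MS = 2.0       # per-unit dead time enforced on emitted trains
THIN_FS_HZ = 1000.0       # Bernoulli thinning grid for spike generation
N_CHANNELS = 4            # tetrode analogue
N_FEATURES = 8            # two features per channel


@dataclass
class SynthConfig:
    """All knobs of the synthetic session; same seed => identical output."""

    seed: int = 0
    # behaviour
    track_length_cm: float = 170.0
    track_width_cm: float = 10.0
    n_laps: int = 10
    run_speed_cm_s: float = 15.0
    end_pause_s: float = 0.5
    pos_noise_cm: float = 0.2
    # units / place tuning (scalars broadcast to n_units; arrays per-unit)
    n_units: int = 30
    field_center_cm: object = None      # default: evenly spaced
    field_width_cm: object = 8.0
    peak_rate_hz: object = 8.0
    baseline_rate_hz: object = 0.5
    directional_gain: object = 0.3      # rate multiplier off the preferred direction
    # theta
    theta_freq_hz: float = 8.0
    phase_kappa: float = 1.0
    preferred_phase_deg: float = 180.0
    # bursts
    burst_prob: float = 0.35
    burst_size_dist: dict = dfield(default_factory=lambda: {2: 0.5, 3: 0.3, 4: 0.15, 5: 0.05})
    intra_burst_isi_ms: tuple = (3.0, 8.0)
    amp_attenuation: float = 0.8
    # rest / ripples
    rest_duration_s: float = 120.0
    ripple_rate_per_min: float = 10.0
    ripple_freq_hz: float = 150.0
    ripple_duration_ms: float = 80.0
    ripple_amp_sd: float = 6.0
    mua_burst_rate_hz: float = 600.0    # summed population rate inside a ripple
    # LFP
    lfp_fs_hz: float = 1627.8
    noise_exponent: float = 1.0
    theta_amp_sd: float = 2.0           # theta amplitude in broadband-SD units

    def __post_init__(self):
        for name in ("track_length_cm", "run_speed_cm_s", "rest_duration_s",
                     "lfp_fs_hz", "theta_freq_hz"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if self.n_laps < 1 or self.n_units < 1:
            raise ConfigurationError("n_laps and n_units must be >= 1")
        if not (0 < self.amp_attenuation <= 1):
            raise ConfigurationError("amp_attenuation must be in (0, 1]")
        if not (0 <= self.burst_prob <= 1):
            raise ConfigurationError("burst_prob must be in [0, 1]")
        if self.phase_kappa < 0 or self.ripple_amp_sd < 0:
            raise ConfigurationError("kappa and ripple_amp_sd are nonnegative")

    def per_unit(self, name: str) -> np.ndarray:
        val = getattr(self, name)
        if val is None and name == "field_center_cm":
            margin = 0.08 * self.track_length_cm
            return np.linspace(margin, self.track_length_cm - margin,
                               self.n_units)
        arr = np.broadcast_to(np.asarray(val, dtype=float), (self.n_units,))
        return arr.copy()

    @property
    def run_duration_s(self) -> float:
        lap = self.track_length_cm / self.run_speed_cm_s
        return self.n_laps * lap + (self.n_laps + 1) * self.end_pause_s


@dataclass
class SynthTruth:
    """Everything the analyses are supposed to recover."""

    units: list                 # per-unit dict of tuning parameters
    ripple_intervals: list      # [(t0, t1)] injected during rest
    spike_burst_id: dict        # unit_id -> int array (-1 = single spike)
    spike_phase_deg: dict       # unit_id -> theta phase at spike time
    spike_injected: dict        # unit_id -> bool array (ripple-coincident MUA)
    epochs: Epochs = None


@dataclass
class SynthSession:
    config: SynthConfig
    position: PositionTrace
    spikes: list                # list[SpikeTrain]
    lfp: LFPSignal
    epochs: Epochs
    truth: SynthTruth


def generate_trajectory(cfg: SynthConfig,
                        rng: np.random.Generator = None) -> PositionTrace:
    """Back-and-forth 1D trajectory embedded in 2D track coordinates.

    Exactly ``n_laps`` end-to-end traversals at ``run_speed_cm_s`` with
    brief pauses at the track ends, sampled at 30 Hz with small tracking
    noise.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    dt = 1.0 / POS_FS_HZ
    lap_t = cfg.track_length_cm / cfg.run_speed_cm_s
    pieces = []
    pause_n = max(1, int(round(cfg.end_pause_s * POS_FS_HZ)))
    at = 0.0
    pieces.append(np.full(pause_n, at))
    for lap in range(cfg.n_laps):
        n = int(round(lap_t * POS_FS_HZ))
        target = cfg.track_length_cm if at == 0.0 else 0.0
        pieces.append(np.linspace(at, target, n, endpoint=False)[1:])
        at = target
        pieces.append(np.full(pause_n, at))
    x = np.concatenate(pieces)
    t = np.arange(len(x)) * dt
    x = np.clip(x + rng.normal(0, cfg.pos_noise_cm, len(x)),
                0, cfg.track_length_cm)
    y = np.clip(cfg.track_width_cm / 2
                + rng.normal(0, cfg.pos_noise_cm, len(x)),
                0, cfg.track_width_cm)
    return PositionTrace(t, x, y)


def theta_phase_deg(cfg: SynthConfig, t: np.ndarray) -> np.ndarray:
    """Ground-truth theta phase (deg): 0 at LFP theta peaks."""
    return (360.0 * cfg.theta_freq_hz * np.asarray(t, float)) % 360.0


def _unit_cluster_model(cfg: SynthConfig, rng: np.random.Generator):
    """Per-unit amplitude template and feature-cluster mean/SD."""
    models = []
    for u in range(cfg.n_units):
        base = rng.uniform(60.0, 120.0)
        channel_profile = rng.dirichlet(np.ones(N_CHANNELS)) * N_CHANNELS
        amp_template = base * channel_profile       # one dominant channel
        feat_mu = rng.normal(0, 40.0, N_FEATURES)
        feat_sd = rng.uniform(3.0, 6.0)
        width = rng.uniform(250.0, 400.0)           # pyramidal-like widths
        models.append((amp_template, feat_mu, feat_sd, width))
    return models


def _expand_bursts(cfg: SynthConfig, events: np.ndarray,
                   rng: np.random.Generator):
    """Expand primary events into bursts; returns (times, burst_id, k_in_burst).

    ``burst_id`` is -1 for single spikes; ``k_in_burst`` is the 0-based
    position of the spike inside its burst (amplitude attenuates as
    ``amp_attenuation ** k``).
    """
    sizes = np.array(sorted(cfg.burst_size_dist))
    probs = np.array([cfg.burst_size_dist[s] for s in sizes], dtype=float)
    probs = probs / probs.sum()
    times, burst_id, k_in = [], [], []
    next_id = 0
    for t0 in events:
        if cfg.burst_prob > 0 and rng.random() < cfg.burst_prob:
            size = int(rng.choice(sizes, p=probs))
            isis = rng.uniform(cfg.intra_burst_isi_ms[0],
                               cfg.intra_burst_isi_ms[1], size - 1) / 1000.0
            tt = t0 + np.concatenate([[0.0], np.cumsum(isis)])
            times.extend(tt)
            burst_id.extend([next_id] * size)
            k_in.extend(range(size))
            next_id += 1
        else:
            times.append(t0)
            burst_id.append(-1)
            k_in.append(0)
    return (np.asarray(times), np.asarray(burst_id, dtype=int),
            np.asarray(k_in, dtype=int))


def generate_spikes(cfg: SynthConfig, pos: PositionTrace,
                    rng: np.random.Generator = None):
    """Place-tuned, theta-modulated, bursty spike trains with ground truth.

    Rate model per unit: ``baseline + peak * gauss(x; c, w) * gain(dir) *
    vm(theta)`` where the von Mises factor ``exp(kappa*cos(th - mu)) /
    I0(kappa)`` has unit mean over phase. The primary event rate is scaled
    down by the expected burst multiplicity so the *emitted* spike rate
    matches the stated tuning.

    Returns ``(trains, truth_fragments)`` where ``truth_fragments`` is a
    per-unit dict of burst membership and spike theta phase.
    """
    if len(pos) == 0:
        raise ConfigurationError("empty trajectory")
    rng = rng or np.random.default_rng(cfg.seed)
    from scipy.special import i0

    run_end = pos.t[-1]
    rest_end = run_end + cfg.rest_duration_s
    dt = 1.0 / THIN_FS_HZ
    tgrid = np.arange(0.0, run_end, dt)
    xg = np.interp(tgrid, pos.t, pos.x)
    dxg = np.gradient(xg, dt)
    going_right = dxg >= 0
    theta = np.deg2rad(theta_phase_deg(cfg, tgrid))
    mu = np.deg2rad(cfg.preferred_phase_deg)
    vm = np.exp(cfg.phase_kappa * np.cos(theta - mu)) / i0(cfg.phase_kappa)

    centers = cfg.per_unit("field_center_cm")
    widths = cfg.per_unit("field_width_cm")
    peaks = cfg.per_unit("peak_rate_hz")
    bases = cfg.per_unit("baseline_rate_hz")
    gains = cfg.per_unit("directional_gain")

    sizes = np.array(sorted(cfg.burst_size_dist))
    probs = np.array([cfg.burst_size_dist[s] for s in sizes], dtype=float)
    probs = probs / probs.sum()
    mean_size = float(np.sum(sizes * probs))
    # expected spikes per primary event
    multiplicity = 1.0 + cfg.burst_prob * (mean_size - 1.0)

    models = _unit_cluster_model(cfg, rng)
    trains, truth_units = [], []
    truth_burst, truth_phase, truth_inj = {}, {}, {}

    for u in range(cfg.n_units):
        pref_right = (u % 2 == 0)
        dir_gain = np.where(going_right == pref_right, 1.0, gains[u])
        spatial = peaks[u] * np.exp(-0.5 * ((xg - centers[u]) / widths[u]) ** 2)
        # theta modulates the unit's entire run-epoch firing, baseline
        # included; the rest-epoch baseline below stays unmodulated
        rate = (bases[u] + spatial * dir_gain) * vm / multiplicity
        emit = rng.random(len(tgrid)) < rate * dt
        run_events = tgrid[emit] + rng.uniform(0, dt, int(emit.sum()))

        # homogeneous baseline firing during rest
        n_rest = rng.poisson(bases[u] / multiplicity * cfg.rest_duration_s)
        rest_events = np.sort(run_end + rng.uniform(0, cfg.rest_duration_s,
                                                    n_rest))
        events = np.sort(np.concatenate([run_events, rest_events]))
        t, burst_id, k_in = _expand_bursts(cfg, events, rng)
        keep = t < rest_end
        t, burst_id, k_in = t[keep], burst_id[keep], k_in[keep]
        order = np.argsort(t, kind="stable")
        t, burst_id, k_in = t[order], burst_id[order], k_in[order]
        keep = _refractory_keep(t)
        t, burst_id, k_in = t[keep], burst_id[keep], k_in[keep]

        amp_template, feat_mu, feat_sd, width_us = models[u]
        atten = cfg.amp_attenuation ** k_in
        jitter = rng.normal(1.0, 0.05, len(t))
        amp = amp_template[None, :] * (atten * jitter)[:, None]
        features = rng.normal(0, feat_sd, (len(t), N_FEATURES)) + feat_mu

        uid = f"u{u:03d}"
        trains.append(SpikeTrain(uid, t, amp, features, width_us))
        truth_units.append({
            "unit_id": uid, "field_center_cm": float(centers[u]),
            "field_width_cm": float(widths[u]),
            "peak_rate_hz": float(peaks[u]),
            "baseline_rate_hz": float(bases[u]),
            "directional_gain": float(gains[u]),
            "preferred_direction": "right" if pref_right else "left",
            "preferred_phase_deg": float(cfg.preferred_phase_deg),
            "phase_kappa": float(cfg.phase_kappa),
            "width_us": float(width_us),
        })
        truth_burst[uid] = burst_id
        truth_phase[uid] = theta_phase_deg(cfg, t)
        truth_inj[uid] = np.zeros(len(t), dtype=bool)

    fragments = {"units": truth_units, "burst_id": truth_burst,
                 "phase_deg": truth_phase, "injected": truth_inj,
                 "models": models}
    return trains, fragments


def _refractory_keep(t: np.ndarray,
                     refractory_ms: float = REFRACTORY_MS) -> np.ndarray:
    """Mask keeping the first spike of any pair closer than the dead time."""
    keep = np.ones(len(t), dtype=bool)
    if len(t) < 2:
        return keep
    last = t[0]
    for i in range(1, len(t)):
        if t[i] - last < refractory_ms / 1000.0:
            keep[i] = False
        else:
            last = t[i]
    return keep


def _pink_noise(n: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    """1/f^beta noise, normalised to unit SD."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec *= f ** (-beta / 2.0)
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def generate_lfp(cfg: SynthConfig, epochs: Epochs, spikes: list,
                 fragments: dict, rng: np.random.Generator = None,
                 max_retries: int = 1000):
    """Pink-noise LFP with run theta and rest ripple packets + MUA bursts.

    Ripple packets are Hanning-windowed sinusoids of the configured
    frequency and duration, with peak amplitude ``ripple_amp_sd`` times
    the background smoothed ripple-band envelope SD. Each packet gets a
    coincident synthetic MUA burst appended to the spike trains (flagged
    in the truth record). Packets are placed without overlap; failure
    after ``max_retries`` draws raises.

    Returns ``(lfp, ripple_intervals)``.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    fs = cfg.lfp_fs_hz
    t_end = max(b for _, b in epochs.run + epochs.rest)
    n = int(round(t_end * fs))
    x = _pink_noise(n, cfg.noise_exponent, rng)
    t = np.arange(n) / fs

    for a, b in epochs.run:
        m = (t >= a) & (t < b)
        x[m] += cfg.theta_amp_sd * np.cos(2 * np.pi * cfg.theta_freq_hz * t[m])

    intervals = []
    params = RippleDetectionParams()
    for a, b in epochs.rest:
        rest_len = b - a
        n_rip = int(round(cfg.ripple_rate_per_min * rest_len / 60.0))
        if n_rip == 0 or cfg.ripple_amp_sd == 0:
            continue
        i0 = int(round(a * fs))
        i1 = int(round(b * fs))
        seg = LFPSignal(x[i0:i1], fs, t0=a)
        _, band_bg, env_mean, env_sd = ripple_envelope(seg, params)

        dur = cfg.ripple_duration_ms / 1000.0
        margin = 0.5
        placed = []
        tries = 0
        while len(placed) < n_rip:
            tries += 1
            if tries > max_retries:
                raise ConfigurationError(
                    "could not place non-overlapping ripples; "
                    "lower ripple_rate_per_min or lengthen rest")
            s = rng.uniform(a + margin, b - margin - dur)
            if all(abs(s - p) > dur + 0.2 for p in placed):
                placed.append(s)
        placed.sort()

        # calibrate the packet so its *smoothed envelope peak* sits
        # ripple_amp_sd SDs above the envelope mean: Gaussian smoothing
        # attenuates the Hanning envelope peak by a known factor
        sigma_t = params.env_smooth_sd_ms / 1000.0
        attn = 0.5 * (1.0 + np.exp(-0.5 * (2 * np.pi * sigma_t / dur) ** 2))
        amp = (env_mean + cfg.ripple_amp_sd * env_sd) / attn
        n_pkt = int(round(dur * fs))
        window = np.hanning(n_pkt)
        for s in placed:
            j0 = int(round(s * fs))
            tt = np.arange(n_pkt) / fs
            packet = amp * window * np.sin(2 * np.pi * cfg.ripple_freq_hz * tt)
            # the event *replaces* the band content under its taper — a
            # ripple dominates the band rather than superposing on an
            # independent background of comparable amplitude
            jloc = j0 - i0
            packet -= window * band_bg[jloc:jloc + n_pkt]
            x[j0:j0 + n_pkt] += packet
            intervals.append((s, s + dur))
            _inject_mua_burst(cfg, spikes, fragments, s, dur, window, rng)

    for tr in spikes:
        order = np.argsort(tr.t, kind="stable")
        keep = _refractory_keep(tr.t[order])
        sel = order[keep]
        tr.t = tr.t[sel]
        tr.amp = tr.amp[sel]
        tr.features = tr.features[sel]
        uid = tr.unit_id
        fragments["burst_id"][uid] = fragments["burst_id"][uid][sel]
        fragments["phase_deg"][uid] = fragments["phase_deg"][uid][sel]
        fragments["injected"][uid] = fragments["injected"][uid][sel]

    return LFPSignal(x, fs), intervals


def _inject_mua_burst(cfg: SynthConfig, spikes: list, fragments: dict,
                      s: float, dur: float, window: np.ndarray,
                      rng: np.random.Generator) -> None:
    """Append an envelope-shaped population burst inside one ripple."""
    n_total = rng.poisson(cfg.mua_burst_rate_hz * dur)
    if n_total == 0:
        return
    w = window / window.sum()
    offsets = rng.choice(len(window), size=n_total, p=w) / len(window) * dur
    unit_idx = rng.integers(0, len(spikes), n_total)
    for k in range(n_total):
        tr = spikes[unit_idx[k]]
        amp_template, feat_mu, feat_sd, _ = fragments["models"][unit_idx[k]]
        t_sp = s + offsets[k]
        tr.t = np.append(tr.t, t_sp)
        tr.amp = np.vstack([tr.amp,
                            amp_template * rng.normal(1.0, 0.05)])
        tr.features = np.vstack([tr.features,
                                 rng.normal(0, feat_sd, N_FEATURES) + feat_mu])
        uid = tr.unit_id
        fragments["burst_id"][uid] = np.append(fragments["burst_id"][uid], -1)
        fragments["phase_deg"][uid] = np.append(
            fragments["phase_deg"][uid], theta_phase_deg(cfg, np.array([t_sp]))[0])
        fragments["injected"][uid] = np.append(fragments["injected"][uid], True)


def generate_session(cfg: SynthConfig) -> SynthSession:
    """Full annotated session: trajectory, spikes, LFP, epochs, truth."""
    rng = np.random.default_rng(cfg.seed)
    pos = generate_trajectory(cfg, rng)
    run_end = float(pos.t[-1]) + 1.0 / POS_FS_HZ
    epochs = Epochs(run=[(0.0, run_end)],
                    rest=[(run_end, run_end + cfg.rest_duration_s)])
    trains, fragments = generate_spikes(cfg, pos, rng)
    lfp, intervals = generate_lfp(cfg, epochs, trains, fragments, rng)
    truth = SynthTruth(units=fragments["units"],
                       ripple_intervals=intervals,
                       spike_burst_id=fragments["burst_id"],
                       spike_phase_deg=fragments["phase_deg"],
                       spike_injected=fragments["injected"],
                       epochs=epochs)
    return SynthSession(cfg, pos, trains, lfp, epochs, truth)
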