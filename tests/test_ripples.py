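import numpy as np
import pytest

from ca1ephys import ripples as R
from ca1ephys.core import LFPSignal, SpikeTrain, interval_overlap, match_intervals

FS = 1627.8


def sine_lfp(freq, dur, amp=1.0, fs=FS):
    t = np.arange(0, dur, 1 / fs)
    return LFPSignal(amp * np.sin(2 * np.pi * freq * t), fs)


def noise_lfp(dur, seed=0, fs=FS):
    rng = np.random.default_rng(seed)
    return LFPSignal(rng.standard_normal(int(dur * fs)), fs)


def synthetic_envelope(bumps, dur_s=20.0, baseline=0.0, fs=FS):
    """Hand-built envelope: (t0_s, dur_ms, height) bumps on a flat floor."""
    env = np.full(int(dur_s * fs), baseline)
    for t0, dur_ms, height in bumps:
        i0 = int(t0 * fs)
        n = int(dur_ms / 1000.0 * fs)
        env[i0:i0 + n] = height
    return env


class TestRippleEnvelope:
    def test_inband_sine_envelope_matches_amplitude(self):
        lfp = sine_lfp(150.0, 5.0, amp=2.0)
        env, _, mean, sd = R.ripple_envelope(lfp)
        mid = env[len(env) // 4: -len(env) // 4]
        np.testing.assert_allclose(mid, 2.0, rtol=0.05)

    def test_silent_signal_zero_envelope(self):
        lfp = LFPSignal(np.zeros(int(5 * FS)), FS)
        env, _, _, _ = R.ripple_envelope(lfp)
        assert np.max(np.abs(env)) < 1e-9

    def test_out_of_band_sine_rejected(self):
        lfp = sine_lfp(60.0, 5.0, amp=2.0)
        env, _, _, _ = R.ripple_envelope(lfp)
        mid = env[len(env) // 4: -len(env) // 4]
        assert np.max(mid) < 0.1

    def test_short_epoch_rejected(self):
        from ca1ephys.core import DataError
        with pytest.raises(DataError):
            R.ripple_envelope(LFPSignal(np.zeros(100), FS))


class TestDetectRipples:
    def test_long_strong_bump_detected(self):
        env = synthetic_envelope([(10.0, 80.0, 10.0)], baseline=1.0)
        lfp = LFPSignal(np.zeros_like(env), FS)
        events = R.detect_ripples(env, lfp, mean=1.0, sd=1.0)
        assert len(events) == 1
        assert events[0].t_start == pytest.approx(10.0, abs=0.01)
        assert events[0].amplitude_sd == pytest.approx(9.0, abs=0.1)

    def test_short_bump_rejected(self):
        env = synthetic_envelope([(10.0, 20.0, 4.5)], baseline=1.0)
        lfp = LFPSignal(np.zeros_like(env), FS)
        assert R.detect_ripples(env, lfp, mean=1.0, sd=1.0) == []

    def test_subthreshold_bump_rejected(self):
        env = synthetic_envelope([(10.0, 80.0, 3.5)], baseline=1.0)
        lfp = LFPSignal(np.zeros_like(env), FS)
        # peak at 2.5 SD above mean never reaches mean + 3 SD
        assert R.detect_ripples(env, lfp, mean=1.0, sd=1.0) == []

    def test_noise_matches_crossing_oracle(self):
        # on pure noise, events = above-mean excursions touching 3 SD and
        # outlasting 30 ms; compare against a direct run-length scan
        env, _, mean, sd = R.ripple_envelope(noise_lfp(60.0, seed=1))
        lfp = LFPSignal(np.zeros_like(env), FS)
        events = R.detect_ripples(env, lfp, mean=mean, sd=sd)
        above = env > mean
        thr = env > mean + 3 * sd
        count = 0
        i = 0
        while i < len(env):
            if above[i]:
                j = i
                while j + 1 < len(env) and above[j + 1]:
                    j += 1
                if thr[i:j + 1].any() and (j - i + 1) > 0.030 * FS:
                    count += 1
                i = j + 1
            else:
                i += 1
        assert len(events) == count


class TestMUAGate:
    def burst_train(self, centers, rng, rate=400.0, dur=0.08, n_units=5,
                    background_hz=2.0, session=60.0):
        trains = []
        for u in range(n_units):
            t = list(rng.uniform(0, session, rng.poisson(background_hz * session)))
            for c in centers:
                t += list(rng.uniform(c, c + dur,
                                      rng.poisson(rate * dur / n_units)))
            trains.append(SpikeTrain(f"u{u}", np.sort(t)))
        return trains

    def test_event_without_spikes_removed(self):
        rng = np.random.default_rng(0)
        trains = self.burst_train([20.0], rng)
        events = [R.RippleEvent(40.0, 40.1, 40.05, 6.0, 1.0, 50.0)]
        gated, _ = R.mua_gate(events, trains, 0.0, 60.0)
        assert gated == []

    def test_event_with_burst_retained(self):
        rng = np.random.default_rng(1)
        trains = self.burst_train([20.0], rng)
        events = [R.RippleEvent(19.99, 20.09, 20.04, 6.0, 1.0, 50.0)]
        gated, _ = R.mua_gate(events, trains, 0.0, 60.0)
        assert len(gated) == 1

    def test_lfp_artifacts_without_spikes_all_removed(self):
        rng = np.random.default_rng(2)
        trains = self.burst_train([], rng)  # background only
        events = [R.RippleEvent(t, t + 0.08, t + 0.04, 6.0, 1.0, 50.0)
                  for t in (10.0, 25.0, 40.0)]
        gated, _ = R.mua_gate(events, trains, 0.0, 60.0)
        assert gated == []


class TestRippleFrequency:
    @pytest.mark.parametrize("freq", [150.0, 200.0])
    def test_packet_frequency(self, freq):
        rng = np.random.default_rng(3)
        n = int(10 * FS)
        x = 0.1 * rng.standard_normal(n)
        t0, dur = 5.0, 0.08
        i0 = int(t0 * FS)
        npkt = int(dur * FS)
        tt = np.arange(npkt) / FS
        x[i0:i0 + npkt] += 5 * np.hanning(npkt) * np.sin(2 * np.pi * freq * tt)
        lfp = LFPSignal(x, FS)
        _, filt, _, _ = R.ripple_envelope(lfp)
        ev = R.RippleEvent(t0, t0 + dur, t0 + dur / 2, 6.0, 1.0, 50.0)
        assert R.ripple_frequency(ev, filt, lfp) == pytest.approx(freq, abs=5.0)

    def test_dominant_component_wins(self):
        n = int(10 * FS)
        x = np.zeros(n)
        t0, dur = 5.0, 0.08
        i0 = int(t0 * FS)
        npkt = int(dur * FS)
        tt = np.arange(npkt) / FS
        x[i0:i0 + npkt] += np.hanning(npkt) * (
            1.0 * np.sin(2 * np.pi * 120 * tt)
            + 3.0 * np.sin(2 * np.pi * 180 * tt))
        lfp = LFPSignal(x, FS)
        _, filt, _, _ = R.ripple_envelope(lfp)
        ev = R.RippleEvent(t0, t0 + dur, t0 + dur / 2, 6.0, 1.0, 50.0)
        assert R.ripple_frequency(ev, filt, lfp) == pytest.approx(180.0, abs=5.0)


class TestRippleMetrics:
    def make_events(self, starts, dur=0.08):
        return [R.RippleEvent(s, s + dur, s + dur / 2, 6.0, 1.0, 50.0,
                              peak_freq_hz=150.0) for s in starts]

    def test_rate(self):
        m = R.ripple_metrics(self.make_events(np.arange(30) * 60.0), 1800.0)
        assert m.rate_per_min == pytest.approx(1.0)

    def test_regular_spacing_iri(self):
        m = R.ripple_metrics(self.make_events(np.arange(10) * 10.0), 100.0)
        assert m.mean_iri_s == pytest.approx(10.0)

    def test_zero_events_flagged(self):
        m = R.ripple_metrics([], 60.0)
        assert m.n_events == 0 and np.isnan(m.mean_iri_s)


class TestRippleUnitStats:
    def test_silent_unit_zero_participation(self):
        events = [R.RippleEvent(s, s + 0.1, s, 6.0, 1.0, 50.0)
                  for s in (1.0, 2.0, 3.0)]
        st = R.ripple_unit_stats(events, SpikeTrain("u", np.array([10.0])))
        assert st.participation == 0.0

    def test_unit_in_every_event(self):
        events = [R.RippleEvent(s, s + 0.1, s, 6.0, 1.0, 50.0)
                  for s in (1.0, 2.0, 3.0)]
        st = R.ripple_unit_stats(events,
                                 SpikeTrain("u", np.array([1.05, 2.05, 3.05])))
        assert st.participation == 1.0
        assert st.spikes_per_ripple == pytest.approx(1.0)

    def test_poisson_participation_closed_form(self):
        rng = np.random.default_rng(4)
        rate, d = 20.0, 0.1
        events = [R.RippleEvent(s, s + d, s, 6.0, 1.0, 50.0)
                  for s in np.arange(0.0, 2000.0, 1.0)]
        t = np.sort(rng.uniform(0, 2000.0, rng.poisson(rate * 2000.0)))
        st = R.ripple_unit_stats(events, SpikeTrain("u", t))
        expected = 1 - np.exp(-rate * d)
        assert st.participation == pytest.approx(expected, abs=0.03)


class TestThresholdSweepAndMUAOnly:
    def test_event_counts_nest_across_thresholds(self, small_session):
        s = small_session
        rest = s.epochs.rest[0]
        sweep = R.threshold_sweep(s.lfp.segment(*rest), s.spikes)
        n2 = len(sweep[2.0]["events"])
        n3 = len(sweep[3.0]["events"])
        n6 = len(sweep[6.0]["events"])
        assert n2 >= n3 >= n6
        assert n3 > 0
        # every 3 SD event overlaps some 2 SD event (nesting)
        for ev in sweep[3.0]["events"]:
            assert any(interval_overlap(ev.t_start, ev.t_end, o.t_start,
                                        o.t_end) > 0
                       for o in sweep[2.0]["events"])

    def test_mua_only_overlaps_lfp_gated(self, small_session):
        s = small_session
        rest = s.epochs.rest[0]
        lfp_events = R.detect_ripples_full(s.lfp.segment(*rest), s.spikes)
        mua_events = R.detect_events_mua_only(s.spikes, *rest)
        a = [(e.t_start, e.t_end) for e in lfp_events]
        b = [(e.t_start, e.t_end) for e in mua_events]
        matched, _, _ = match_intervals(a, b)
        jaccard = matched / (len(a) + len(b) - matched)
        assert jaccard >= 0.8

    def test_no_spikes_no_mua_events(self):
        assert R.detect_events_mua_only([], 0.0, 60.0) == []

    def test_single_population_burst_single_event(self):
        rng = np.random.default_rng(5)
        trains = []
        for u in range(5):
            bg = rng.uniform(0, 60.0, rng.poisson(120))
            burst = rng.uniform(30.0, 30.08, 30)
            trains.append(SpikeTrain(f"u{u}", np.sort(np.concatenate([bg, burst]))))
        events = R.detect_events_mua_only(trains, 0.0, 60.0)
        assert len(events) == 1
        assert events[0].t_start <= 30.0 <= events[0].t_end
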