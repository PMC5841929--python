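import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ca1ephys as ce

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_session():
    """One shared small synthetic session with injected ripples."""
    cfg = ce.SynthConfig(seed=7, n_units=8, n_laps=4, rest_duration_s=60.0)
    return ce.generate_session(cfg)


@pytest.fixture(scope="session")
def analyzed(small_session):
    s = small_session
    bundle = {"position": s.position, "spikes": s.spikes, "lfp": s.lfp,
              "epochs": s.epochs, "truth": s.truth}
    return ce.analyze_session(bundle)


def uniform_trajectory(duration_s=60.0, speed=15.0, track=170.0, fs=30.0):
    """Deterministic triangle-wave trajectory covering the track."""
    t = np.arange(0.0, duration_s, 1.0 / fs)
    period = 2 * track / speed
    phase = (t % period) / period
    x = np.where(phase < 0.5, 2 * track * phase, 2 * track * (1 - phase))
    y = np.full_like(x, 5.0)
    return ce.PositionTrace(t, x, y)
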