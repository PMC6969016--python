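import numpy as np
import pytest

from scentmark import AccelTrace, BehaviourClass, LabelTrack, SimConfig, simulate
from scentmark.synthetic import simulate_accel


def make_trace(signal: np.ndarray, rate_hz: float = 50.0, t0: float = 0.0) -> AccelTrace:
    """AccelTrace from an (n, 3) array."""
    sig = np.atleast_2d(np.asarray(signal, dtype=float))
    t = t0 + np.arange(len(sig)) / rate_hz
    return AccelTrace(t=t, x=sig[:, 0], y=sig[:, 1], z=sig[:, 2], rate_hz=rate_hz)


def toy_three_class(n_left=10, n_right=10, n_other=20, rate_hz=50.0):
    """Tiny linearly separable trace with LEFT/RIGHT/OTHER blocks."""
    rng = np.random.default_rng(99)
    sig = np.concatenate(
        [
            np.tile([0.0, -1.0, 0.0], (n_left, 1)),
            np.tile([0.0, 1.0, 0.0], (n_right, 1)),
            np.tile([0.0, 0.0, -1.0], (n_other, 1))
            + rng.normal(0, 0.05, (n_other, 3)),
        ]
    )
    trace = make_trace(sig, rate_hz=rate_hz)
    dt = 1.0 / rate_hz
    labels = LabelTrack(
        [
            (0.0, n_left * dt, BehaviourClass.LEFT_LEG),
            (n_left * dt, (n_left + n_right) * dt, BehaviourClass.RIGHT_LEG),
            (
                (n_left + n_right) * dt,
                (n_left + n_right + n_other) * dt,
                BehaviourClass.OTHER,
            ),
        ]
    )
    return trace, labels


@pytest.fixture(scope="session")
def male_sim():
    """A 30 min male simulation with defaults-like noise, reused broadly."""
    cfg = SimConfig(
        seed=11, duration_s=1800.0, marks_per_hour=10.0, noise_sd_g=0.1,
        sex="male", gps_jitter_sd_m=0.0, foray_prob_per_min=0.1,
    )
    return cfg, simulate(cfg)


@pytest.fixture(scope="session")
def female_sim():
    cfg = SimConfig(
        seed=12, duration_s=1800.0, marks_per_hour=10.0, noise_sd_g=0.1,
        sex="female", gps_jitter_sd_m=0.0,
    )
    return cfg, simulate(cfg)


@pytest.fixture(scope="session")
def noisefree_sim():
    cfg = SimConfig(
        seed=13, duration_s=1200.0, marks_per_hour=12.0, noise_sd_g=0.0,
        sex="male",
    )
    return cfg, simulate_accel(cfg)
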