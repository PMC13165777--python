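import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_scene():
    """A 35 s, 120x160 scene with default motion/shadow/noise (one episode
    plus change), shared across tests that only need a realistic scene."""
    from facepulse.synth import SceneConfig, make_scene

    cfg = SceneConfig(duration=35.0, hr_bpm=72.0, seed=11)
    video, truth = make_scene(cfg)
    return cfg, video, truth


@pytest.fixture(scope="session")
def still_scene():
    """A motionless, noiseless scene for exact-signal checks."""
    from facepulse.synth import MotionSpec, SceneConfig, make_scene

    cfg = SceneConfig(duration=32.0, hr_bpm=72.0, seed=4, noise_sd=0.0,
                      motion=MotionSpec(drift_amplitude=0.0, jitter_sd=0.0,
                                        rot_drift_amplitude=0.0,
                                        rot_jitter_sd=0.0))
    video, truth = make_scene(cfg)
    return cfg, video, truth


@pytest.fixture(scope="session")
def trained_selector():
    """Pulse/noise selector trained on a compact synthetic source corpus."""
    from facepulse.selection import train_selector
    from facepulse.synth import make_source_corpus

    F, y, g = make_source_corpus(n_subjects=6, mixtures_per_subject=3, seed=0)
    model, report = train_selector(F, y, g, seed=0)
    return model, report


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
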