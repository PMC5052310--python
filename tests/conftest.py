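import pytest

from crir import KnobSettings, RecordingConfig, build_protocol, simulate_recording

DEFAULT_SETTINGS = KnobSettings(50, 65)


@pytest.fixture(scope="session")
def protocol9():
    """The clinical 9-step 0.1–1000 cd/m^2 protocol."""
    return build_protocol()


@pytest.fixture(scope="session")
def noiseless_cfg():
    return RecordingConfig(noise_rms_v=0.0)


@pytest.fixture(scope="session")
def noiseless_trace(protocol9, noiseless_cfg):
    """Noiseless 9-step recording at the mid-range default settings."""
    return simulate_recording(protocol9, DEFAULT_SETTINGS, cfg=noiseless_cfg)


@pytest.fixture(scope="session")
def noisy_trace(protocol9):
    """Default-noise 9-step recording at the mid-range default settings."""
    return simulate_recording(protocol9, DEFAULT_SETTINGS, cfg=RecordingConfig(seed=7))
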