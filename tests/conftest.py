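import numpy as np
import pytest

from cardioconn.cardiac import BeatRecord
from cardioconn.simulate import AutonomicSimConfig, BrainSimConfig, generate_beats


@pytest.fixture(scope="session")
def constant_beats() -> BeatRecord:
    """10 minutes of perfectly regular 800 ms beats."""
    cfg = AutonomicSimConfig(
        hf_amp_ms=0, lf_amp_ms=0, noise_sd_ms=0, artifact_rate=0, seed=0
    )
    return generate_beats(cfg).record


@pytest.fixture(scope="session")
def modulated_beats() -> BeatRecord:
    """Noise-free 0.25 Hz / 30 ms respiratory-band modulation."""
    cfg = AutonomicSimConfig(
        hf_amp_ms=30, hf_freq_hz=0.25, lf_amp_ms=0, noise_sd_ms=0, artifact_rate=0, seed=1
    )
    return generate_beats(cfg).record


@pytest.fixture(scope="session")
def small_brain_cfg() -> BrainSimConfig:
    return BrainSimConfig(seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
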