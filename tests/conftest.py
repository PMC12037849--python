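import numpy as np
import pytest

from imusa import detect_all, get_preset, simulate


@pytest.fixture(scope="session")
def moderate_run():
    """One-hour moderate-SA scenario: (spec, recording, truth, detection)."""
    spec = get_preset("moderate_sa", duration_s=3600.0, seed=11)
    recording, truth = simulate(spec)
    result = detect_all(recording)
    return spec, recording, truth, result


@pytest.fixture(scope="session")
def posture_run():
    """Same events as moderate_sa but with posture rotations."""
    spec = get_preset("posture_switcher", duration_s=3600.0, seed=11)
    recording, truth = simulate(spec)
    result = detect_all(recording)
    return spec, recording, truth, result


@pytest.fixture(scope="session")
def normal_run():
    """Event-free one-hour night."""
    spec = get_preset("normal_night", duration_s=3600.0, seed=11)
    recording, truth = simulate(spec)
    result = detect_all(recording)
    return spec, recording, truth, result


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
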