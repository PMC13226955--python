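import numpy as np
import pytest

import remloop as rl


@pytest.fixture(scope="session")
def model() -> rl.AnimalModel:
    return rl.AnimalModel.default()


@pytest.fixture(scope="session")
def baseline(model) -> rl.BaselineRecording:
    """Two-hour labeled synthetic baseline shared across tests."""
    return rl.record_baseline(model, duration=2 * 3600.0, seed=11)


@pytest.fixture(scope="session")
def thresholds(baseline, model) -> rl.Thresholds:
    thr, _ = rl.calibrate(baseline, animal_id=model.animal_id)
    return thr


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
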