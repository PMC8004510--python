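import numpy as np
import pytest

import eegstream as es


@pytest.fixture(scope="session")
def setup32():
    """Default desk-scale study setup: 32 electrodes, 20 mm grid, leadfield."""
    return es.example_setup()


@pytest.fixture(scope="session")
def leadfield(setup32):
    return setup32[3]


@pytest.fixture(scope="session")
def study():
    """Full simulate -> calibrate -> stream -> analyze chain (seeded)."""
    return es.run_validation_study(seed=2)


@pytest.fixture(scope="session")
def calibration_sim(setup32):
    """A 60 s resting calibration recording with artifacts, plus its filters."""
    electrodes, model, grid, lf = setup32
    rec, truth = es.simulate_recording(es.calibration_spec(lf, 60.0, seed=0), lf)
    cfg = es.CalibrationConfig(adjacency_mm=60.0, noise_cov="identity", seed=0)
    filters, report = es.run_calibration(rec, lf, electrodes, cfg)
    return rec, truth, filters, report


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
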