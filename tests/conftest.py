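import numpy as np
import pytest
from hypothesis import settings

import enoseflow as ef

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def noiseless_params():
    """Simulator with every stochastic component switched off."""
    return ef.SimParams(
        noise_sd_voltage=0.0,
        flow_noise_sd=0.0,
        run_gain_jitter=0.0,
        run_baseline_jitter_voltage=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def default_result():
    """One full default experiment (seed 1), shared across tests.

    This is the package's reference synthetic study: 6 concentrations x
    6 flows x 2 replicates, 5-minute runs at 10 Hz, all models trained.
    """
    return ef.run_pipeline(ef.ExperimentConfig().with_seed(1))


@pytest.fixture
def small_samples():
    """180 calibration samples from a quick noiseless-ish short-run dataset."""
    params = ef.SimParams(seed=5)
    design = ef.generate_design()
    runs = ef.simulate_dataset(design, params, sample_rate_hz=10.0, duration_s=60.0)
    train = [r for r in runs if r.condition.split == "train"]
    return ef.build_calibration_samples(train, window=21, span=0.3)


def make_samples(x1, x2, y, kind="mean"):
    """Wrap plain arrays as calibration samples for model-level tests."""
    cond = ef.Condition(50.0, 1000.0, 1)
    return [
        ef.CalibrationSample(x1=float(a), x2=float(b), y=float(c), feature_kind=kind, condition=cond)
        for a, b, c in zip(np.asarray(x1), np.asarray(x2), np.asarray(y))
    ]
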