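import warnings

import numpy as np
import pytest

import hyperspike as hs


def pytest_configure(config):
    # model-fit fallback warnings (few isolated spikes at 1 Hz firing) are
    # expected throughout the suite
    warnings.filterwarnings("ignore", message="only .* isolated spikes")


@pytest.fixture(scope="session")
def reference_condition():
    """The high-sampling-rate benchmark condition: 60 Hz, 1 Hz firing,
    alpha = 1, SNR 5, tau2 = 0.5 s; 10 cells split 5 train / 5 test."""
    cfg = hs.SimulationConfig(firing_rate=1.0, tau2=0.5, alpha=1.0, snr=5.0,
                              sampling_rate=60.0, seed=1)
    train, test = hs.generate_dataset(cfg, split=True)
    return cfg, train, test


@pytest.fixture(scope="session")
def reference_pipeline(reference_condition):
    cfg, train, test = reference_condition
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = hs.SupervisedPipeline(train, seed=0).fit()
    return result


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
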