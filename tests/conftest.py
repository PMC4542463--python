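import numpy as np
import pytest

from laminaris import (ProtocolConfig, SiteGroundTruth, simulate_spike_site)


@pytest.fixture(scope="session")
def trough_type_gt():
    """A trough-type site: CD 160 μs contra-leading, CP 0.46, CF 700 Hz."""
    return SiteGroundTruth(cf=700.0, cd_true=160.0, cp_true=0.46, seed=42)


@pytest.fixture(scope="session")
def multi_frequency_protocol():
    """ITD tests at six frequencies spanning 500–1000 Hz, 20 trials each."""
    return ProtocolConfig(frequencies=(500., 600., 700., 800., 900., 1000.),
                          n_trials=20)


@pytest.fixture(scope="session")
def trough_type_site(trough_type_gt, multi_frequency_protocol):
    return simulate_spike_site(trough_type_gt, multi_frequency_protocol)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
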