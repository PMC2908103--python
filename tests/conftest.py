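import pytest

from pmtcal import (ScannerResponseModel, SimulationConfig, make_slide_layout,
                    simulate_scan)

#: Fitted characteristics of an Agilent scanner, Cy3 channel, PMT gain 100;
#: the canonical ground truth used across the suite.
AGILENT_CY3_100 = ScannerResponseModel(B=106, a=0.95, g=11.90,
                                       channel="Cy3", pmt_gain=100)


@pytest.fixture(scope="session")
def truth():
    return AGILENT_CY3_100


@pytest.fixture(scope="session")
def layout():
    return make_slide_layout(replicates_per_column=20)


@pytest.fixture(scope="session")
def noisefree_obs(truth, layout):
    cfg = SimulationConfig(truth=truth, seed=1, noise_cv=0.0)
    return simulate_scan(layout, cfg)


@pytest.fixture(scope="session")
def noisy_obs(truth, layout):
    cfg = SimulationConfig(truth=truth, seed=42, noise_cv=0.10)
    return simulate_scan(layout, cfg)
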