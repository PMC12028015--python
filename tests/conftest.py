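import numpy as np
import pytest

import cordquant as cq


@pytest.fixture(scope="session")
def atlas():
    return cq.build_toy_atlas((2000.0, 1500.0), 10)


@pytest.fixture(scope="session")
def small_atlas():
    """Small frame keeps per-test simulation cheap."""
    return cq.build_toy_atlas((800.0, 600.0), 4)


@pytest.fixture(scope="session")
def config():
    return cq.SimulationConfig(seed=12345)


@pytest.fixture(scope="session")
def control_section(atlas, config):
    """One control section shared by read-only tests."""
    return cq.simulate_section(atlas, config, None, section_id="ctrl-0")


@pytest.fixture(scope="session")
def noiseless_config():
    """No pixel noise, no PSF: rendered discs are exact."""
    return cq.SimulationConfig(seed=777, noise_sd=0.0, psf_sigma_px=0.0)


@pytest.fixture(scope="session")
def noiseless_section(atlas, noiseless_config):
    return cq.simulate_section(atlas, noiseless_config, None, section_id="clean-0")


def jittered_sets(truth, atlas, k, sensitivity, jitter, fp_rate=0.0, seed0=0):
    """K simulated observer analyses of the same ground truth."""
    sets = []
    for i in range(k):
        profile = cq.ObserverProfile(
            sensitivity=sensitivity, fp_rate=fp_rate, jitter_sd=jitter, seed=seed0 + i
        )
        sets.append(cq.simulate_observer(truth, atlas, profile, source_id=f"obs{i + 1}"))
    return sets
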