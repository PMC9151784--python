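import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # sw_oracle helper

from xenosynt.pipeline import run_hgt_pipeline
from xenosynt.simulate import load_scenario, simulate_dataset


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_dataset("small3", 11)


@pytest.fixture(scope="session")
def panel_bundle():
    """The full nine-species scenario, noise-free, seed 1."""
    return simulate_dataset("myriapod9", 1)


@pytest.fixture(scope="session")
def panel_result(panel_bundle):
    return run_hgt_pipeline(panel_bundle)


@pytest.fixture(scope="session")
def small_cfg():
    return load_scenario("small3")


@pytest.fixture(scope="session")
def panel_cfg():
    return load_scenario("myriapod9")
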