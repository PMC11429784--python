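import math

import numpy as np
import pytest

import bptsim as b
from bptsim.scenarios import ScenarioConfig, gen_translation_sweep


@pytest.fixture(scope="session")
def bore():
    return b.BoreModel(radius=0.35, length=1.35, end_reflection=1.0)


@pytest.fixture(scope="session")
def te11():
    return b.WaveguideMode("TE", 1, 1, 0.35)


@pytest.fixture(scope="session")
def source_24ghz():
    return b.SourceSpec(position=(0.25, -math.pi / 2, -0.55), frequency=2400e6)


@pytest.fixture(scope="session")
def sweep_result():
    """One-period translation sweep shared by the scenario-level tests."""
    cfg = ScenarioConfig(kind="translation_sweep", seed=7,
                         params={"n_repeats": 1, "n_positions": 41})
    return gen_translation_sweep(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
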