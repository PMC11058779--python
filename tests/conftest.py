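import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from riverhealth.synthetic import ScenarioConfig, make_bundle


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic study bundle (41 sites, 50 species), fixed seed."""
    return make_bundle(ScenarioConfig(), random_state=1)


@pytest.fixture(scope="session")
def small_guilds():
    """Six species in four entities, covering all three guild dimensions."""
    return pd.DataFrame(
        {
            "species_id": ["a", "b", "c", "d", "e", "f"],
            "trophic": ["Omn", "Omn", "Ins", "Ins", "Car", "Omn"],
            "habitat": ["WC", "WC", "RB", "RB", "BT", "RB-WC"],
            "tolerance": ["TS", "TS", "SS", "SS", "IS", "IS"],
            "native": [True, False, True, True, True, True],
        }
    )


@pytest.fixture(scope="session")
def small_abundance():
    return pd.DataFrame(
        {
            "a": [3, 0, 5],
            "b": [4, 0, 1],
            "c": [0, 2, 7],
            "d": [1, 3, 0],
            "e": [0, 1, 2],
            "f": [10, 20, 30],
        },
        index=pd.Index(["s1", "s2", "s3"], name="site_id"),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
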