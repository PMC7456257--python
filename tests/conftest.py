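import dataclasses

import pandas as pd
import pytest
from hypothesis import settings

from saplingcrown.io import Dataset, model_frame
from saplingcrown.models import ProfileParams
from saplingcrown.synthetic import StandConfig, generate_stand

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

#: published selected-quantile coefficient rows used throughout the tests
CUT_SELECTED = ProfileParams("power_exp_full", (0.4030, 0.4751, 1.1811, -0.5538, -0.9125))
UNCUT_SELECTED = ProfileParams("power_exp_full", (1.2834, 0.3950, 1.2543, -0.1097, -1.8092))


@pytest.fixture(scope="session")
def stand():
    """Default-size synthetic stand (49 + 30 saplings), fixed seed."""
    return generate_stand(dataclasses.replace(StandConfig(), seed=20))


@pytest.fixture(scope="session")
def cut_frame(stand):
    return model_frame(stand, strip="shelterwood_cut")


@pytest.fixture()
def tiny_dataset():
    """Hand-built two-sapling dataset with exactly known geometry."""
    saplings = pd.DataFrame({
        "sapling_id": ["s1", "s2"],
        "strip_type": ["shelterwood_cut", "uncut"],
        "dbh_cm": [2.0, 1.5], "ht_m": [2.5, 2.0], "cl_m": [2.0, 1.5],
        "excluded_flag": [0, 0],
    })
    branches = pd.DataFrame({
        "sapling_id": ["s1", "s1", "s1", "s2"],
        "whorl_index": [1, 1, 2, 1],
        "l_m": [1.0, 1.0, 1.5, 0.8],
        "bl_cm": [45.0, 55.0, 60.0, 40.0],
        "bc_cm": [40.0, 50.0, 55.0, 36.0],
        "va_deg": [90.0, 60.0, 80.0, 90.0],
        "bd_mm": [6.0, 8.0, 9.0, 5.0],
        "azimuth_deg": [10.0, 200.0, 90.0, 350.0],
    })
    from saplingcrown.io import _derive_frame
    return Dataset(saplings=saplings, branches=_derive_frame(branches, saplings))
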