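import numpy as np
import pytest

import shp2kin as sk
from shp2kin import coupled_model as cm


@pytest.fixture(scope="session")
def wt_scheme() -> sk.ConfSelScheme:
    """Conformational-selection scheme with the WT landscape and rates."""
    return sk.preset_scheme("wt")


@pytest.fixture(scope="session")
def e76k_scheme() -> sk.ConfSelScheme:
    return sk.preset_scheme("e76k")


@pytest.fixture(scope="session")
def engine() -> sk.TwoSiteParams:
    return cm.default_engine()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
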