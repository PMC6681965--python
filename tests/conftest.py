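import warnings

import numpy as np
import pytest

from cocomorph import (CoccolithSpec, OpticalConstants, default_calibration)
from cocomorph.synth import make_thickness_map, scale_to_mean_thickness

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def constants() -> OpticalConstants:
    return OpticalConstants()


@pytest.fixture(scope="session")
def cal():
    return default_calibration()


@pytest.fixture(scope="session")
def ehux_map(constants):
    """One E. huxleyi-scale model coccolith (L=2.7 μm, T̄=0.07 μm)."""
    spec = scale_to_mean_thickness(
        CoccolithSpec(length=2.7), 0.07, constants)
    return make_thickness_map(spec, constants)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)
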