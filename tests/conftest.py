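import numpy as np
import pytest

from flowmax.fcyton import FcytonParams
from flowmax.fluorescence import FluorParams
from flowmax.synthetic import GeneratorConfig, generate_course


@pytest.fixture(scope="session")
def wt_params() -> FcytonParams:
    """A wildtype-like stimulated B-cell parameter set."""
    return FcytonParams(
        N=1e4, F0=0.85, Dmu=3.5, Dsigma=1.0,
        Ediv0=40.0, SDdiv0=10.0, Ediv1=10.0, SDdiv1=4.0,
        Edie0=60.0, SDdie0=20.0, Edie1=80.0, SDdie1=30.0,
    )


@pytest.fixture(scope="session")
def low_cv_fluor() -> FluorParams:
    return FluorParams(cv=0.18, r=0.5, b=100.0, s=0.0, i0=2e5, g_max=8)


@pytest.fixture(scope="session")
def small_course(wt_params, low_cv_fluor):
    """A deterministic five-point noise-free course for fast tests."""
    cfg = GeneratorConfig(schedule="five_point")
    return generate_course(truth=(wt_params, low_cv_fluor), cfg=cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
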