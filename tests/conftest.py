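import numpy as np
import pytest

from wzpop import DemographicParams, PopulationState


@pytest.fixture
def default_params() -> DemographicParams:
    """alpha=0.04, sigma_a=0.6, sigma0*phi=1.2 (lambda_inf = 1.2)."""
    return DemographicParams(alpha=0.04, sigma0=1.0, sigma_a=0.6, phi=1.2)


@pytest.fixture
def half_half() -> PopulationState:
    """The canonical founder: ZZ = WZ = 50%, no intersex, no WW."""
    return PopulationState(zz=0.5, is_=0.0, wz=0.5, ww=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)
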