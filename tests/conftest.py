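import numpy as np
import pytest

from vertigrow import ColumnGrid, GrowthParams, SyntheticSpec, TransportParams


@pytest.fixture(scope="session")
def measured_params() -> GrowthParams:
    """Best-fit rates for a measured A. veronii colony (alpha, beta in 1/h, L in um)."""
    return GrowthParams(alpha=0.86, beta=0.051, L=13.17)


@pytest.fixture(scope="session")
def unit_transport() -> TransportParams:
    return TransportParams(D_R=1.0, epsilon=1.0, R_star=1.0)


@pytest.fixture(scope="session")
def grid256() -> ColumnGrid:
    return ColumnGrid(256)


@pytest.fixture(scope="session")
def noiseless_spec() -> SyntheticSpec:
    return SyntheticSpec(noise_sd_rel=0.0, noise_sd_abs=0.0)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
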