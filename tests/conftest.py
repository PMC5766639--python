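import numpy as np
import pytest

from spfmri import (
    BValueScheme,
    DWISeries,
    IVIMParams,
    ToftsParams,
    ivim_signal,
    population_aif,
)


@pytest.fixture(scope="session")
def scheme():
    return BValueScheme.default()


@pytest.fixture(scope="session")
def ivim_example():
    return IVIMParams(f=0.1, D=1e-3, D_star=10e-3)


@pytest.fixture(scope="session")
def tofts_example():
    # realistic high-grade test point
    return ToftsParams(Ktrans=0.14, v_e=0.204, v_p=0.055)


@pytest.fixture
def make_series(scheme):
    def _make(params: IVIMParams, S0: float = 1.0) -> DWISeries:
        return DWISeries(scheme, ivim_signal(params, scheme.as_array(), S0))

    return _make


@pytest.fixture(scope="session")
def aif():
    return population_aif()


@pytest.fixture(scope="session")
def dce_times():
    # 5 s sampling over 4 min
    return np.arange(0.0, 4.0 + 1e-9, 5.0 / 60.0)
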