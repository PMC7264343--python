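import numpy as np
import pytest

from coastcarb import make_forcing, run, solve_from_pco2_ta
from coastcarb.boxmodel import ModelParams

REF = dict(pCO2=395.0, TA=2280.0, T=18.0, S=35.0)


@pytest.fixture(scope="session")
def ref_state():
    """The open-system reference parcel (pCO2 395, TA 2280, S 35, 18 degC)."""
    return solve_from_pco2_ta(REF["pCO2"], REF["TA"], REF["T"], REF["S"])


@pytest.fixture(scope="session")
def nwa_forcing():
    forcing, chl = make_forcing("nwa", year_days=365, seed=1)
    return forcing, chl


@pytest.fixture(scope="session")
def nwa_trajectory(nwa_forcing):
    forcing, _ = nwa_forcing
    return run(forcing, ModelParams.for_region("nwa"))


@pytest.fixture(scope="session")
def sab_trajectory():
    forcing, _ = make_forcing("sab", year_days=365, seed=1)
    return run(forcing, ModelParams.for_region("sab"))


@pytest.fixture(scope="session")
def solver_grid():
    """T x S x TA x DIC/TA grid of > 500 states for oracle comparisons."""
    temps = np.array([0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0])
    sals = np.array([20.0, 25.0, 30.0, 35.0, 37.0])
    tas = np.array([2000.0, 2150.0, 2300.0, 2450.0])
    ratios = np.array([0.80, 0.85, 0.90, 0.95])
    return [
        (t, s, ta, ta * r)
        for t in temps
        for s in sals
        for ta in tas
        for r in ratios
    ]
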