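import numpy as np
import pytest

from asdkit import default_compounds
from asdkit.core import CompoundThermo
from asdkit.pcsaft import load_pcsaft_params


@pytest.fixture(scope="session")
def compounds():
    return default_compounds()


@pytest.fixture(scope="session")
def ibu(compounds):
    return compounds["IBU"]


@pytest.fixture(scope="session")
def kolva64(compounds):
    return compounds["KOLVA64"]


@pytest.fixture(scope="session")
def pcsaft_params():
    return load_pcsaft_params()


def make_pair(m: float) -> tuple[CompoundThermo, CompoundThermo]:
    """API/polymer records whose molar-volume ratio is exactly m."""
    api = CompoundThermo(name="API", role="API", Mw=100.0, rho=1.0, Tg=230.0,
                         Tm=350.0, dHfus=25000.0, dCp=70.0)
    poly = CompoundThermo(name="POLY", role="polymer", Mw=100.0 * m, rho=1.0,
                          Tg=380.0)
    return api, poly


@pytest.fixture(autouse=True)
def _quiet_numerics():
    # the EOS density scan legitimately evaluates log/sqrt outside their
    # domains while bracketing; those lanes are discarded
    with np.errstate(invalid="ignore", divide="ignore"):
        yield
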