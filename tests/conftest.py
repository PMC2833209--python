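import numpy as np
import pytest

from eomvisc.base_models import (
    BaseModelParams,
    LengthTension,
    RelaxationSpectrum,
    ViscosityLaw,
)
from eomvisc.io_cli import load_fixture, synthetic_base_model

G_DEFAULT = (0.30, 0.25, 0.20, 0.15, 0.12, 0.10, 0.08)


@pytest.fixture(scope="session")
def linear_qlv():
    """QLV with a linear length-tension curve, no viscosity: a linear system."""
    return BaseModelParams(
        kind="qlv",
        lt=LengthTension(c0=0.5, c1=1.5, c2=0.0, c3=0.0),
        spectrum=RelaxationSpectrum(g=G_DEFAULT, alpha=1.0),
        viscosity=ViscosityLaw(),
        viscous_enabled=False,
    )


@pytest.fixture(scope="session")
def qlv_synth():
    return synthetic_base_model("qlv")


@pytest.fixture(scope="session")
def aqlv_synth():
    return synthetic_base_model("aqlv")


@pytest.fixture(scope="session")
def fx_qlv_m4lr():
    return load_fixture("qlv_anlv", "m4LR")


@pytest.fixture(scope="session")
def fx_aqlv_m4lr():
    return load_fixture("aqlv_anlv", "m4LR")


@pytest.fixture(scope="session")
def fx_qlv_m2sr():
    return load_fixture("qlv_anlv", "m2SR")
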