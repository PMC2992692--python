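import numpy as np
import pytest

from gastroflow.geometry import build_geometry, default_params, tube_params
from gastroflow.motility import MotilityModel


@pytest.fixture(scope="session")
def stomach():
    """The calibrated average-stomach geometry (built once per session)."""
    return build_geometry(default_params())


@pytest.fixture(scope="session")
def tube():
    """Straight horizontal tube: radius 1 cm, length 10 cm."""
    return build_geometry(tube_params(length=10.0, radius=1.0))


@pytest.fixture(scope="session")
def model(stomach):
    return MotilityModel(stomach)


@pytest.fixture(scope="session")
def tube_model(tube):
    return MotilityModel(tube)
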