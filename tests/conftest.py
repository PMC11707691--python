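import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from serialindex.geometry import DetectorGeometry
from serialindex.lattice import cell_from_parameters
from serialindex.simulate import LYSOZYME_CELL, default_geometry

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_geometry() -> DetectorGeometry:
    return default_geometry()


@pytest.fixture
def small_geometry() -> DetectorGeometry:
    """Tiny detector for exhaustive per-pixel oracles."""
    return DetectorGeometry(
        n_fast=64,
        n_slow=48,
        pixel_size=0.075,
        camera_length=100.0,
        beam_centre_fast=31.25,
        beam_centre_slow=24.5,
        wavelength=1.0,
    )


@pytest.fixture(scope="session")
def lysozyme_cell():
    return cell_from_parameters(*LYSOZYME_CELL)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
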