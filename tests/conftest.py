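import numpy as np
import pytest

from glintloc.ahrtf import ParametricBeam, make_trajectory
from glintloc.config import ExperimentConfig, PinnaConfig
from glintloc.directions import make_direction_grid
from glintloc.templates import build_templates


@pytest.fixture(scope="session")
def small_cfg() -> ExperimentConfig:
    """Desk-test configuration: small grid, coarse sweep, few realizations."""
    return ExperimentConfig(
        grid_size=60,
        flutter_rates_hz=(20.0, 60.0, 100.0, 200.0),
        echo_strengths_db=(0.0, 20.0, 40.0, 60.0),
        n_realizations=3,
        pinnae=PinnaConfig(n_positions=40),
    )


@pytest.fixture(scope="session")
def tiny_templates(small_cfg):
    """Template set on a 60-direction grid with the default synthetic beams."""
    from glintloc.experiments import build_default_templates

    return build_default_templates(small_cfg)


@pytest.fixture(scope="session")
def micro_templates():
    """Very small template set (8 directions, 20 stroke positions) for oracles."""
    grid = make_direction_grid(8)
    emission = ParametricBeam(60.0)
    ear_l = ParametricBeam(60.0, -20.0, 10.0)
    ear_r = ParametricBeam(60.0, 20.0, 10.0)
    tl = make_trajectory("left", n_positions=20)
    tr = make_trajectory("right", n_positions=20)
    return build_templates(emission, ear_l, ear_r, tl, tr, grid)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
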