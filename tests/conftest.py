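import numpy as np
import pytest

from vectorpsf import SimulationConfig, validate


@pytest.fixture
def default_config() -> SimulationConfig:
    return validate({})


@pytest.fixture
def small_grid() -> dict:
    """Fast grid for tests that only need qualitative structure."""
    return {"nx": 17, "ny": 17, "nz": 9, "extent_xy": 800.0, "extent_z": 1500.0,
            "n_theta": 21, "n_phi": 21}


@pytest.fixture
def circular_beam() -> dict:
    return {"polarization": {"epsilon": np.pi / 4}}


def donut_config(extra_system=None, **grid):
    """Vortex donut with co-rotating circular polarization."""
    cfg = {
        "beam": {
            "polarization": {"epsilon": np.pi / 4},
            "mask": {"kind": "vortex", "charge_q": 1},
        },
    }
    if extra_system:
        cfg["system"] = extra_system
    if grid:
        cfg["grid"] = grid
    return validate(cfg)
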