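"""Shared small fixtures; everything is generated programmatically."""

import numpy as np
import pytest
from hypothesis import settings

from myofield import experiments as ex
from myofield import geometry as geo

settings.register_profile("det", derandomize=True, deadline=None)
settings.load_profile("det")


@pytest.fixture(scope="session")
def tiny_config():
    """Small, fast configuration exercising the whole pipeline."""
    return ex.ExperimentConfig(
        L=1.6, W=0.6, H=0.8,
        depth=0.2,
        spacing=0.2,
        air_padding=1.6,
        duration=6.0,
        channel=(1.0, 0.4),
        line_xl=1.0,
        nmj_xl=0.4,
        mu1_xt_par=0.4,
    )


@pytest.fixture(scope="session")
def tiny_grid():
    return geo.build_grid(L=1.0, W=0.6, H=0.8, spacing=0.2, air_padding=1.0)


@pytest.fixture(scope="session")
def tiny_model(tiny_grid):
    fibres = geo.uniform_fibres(tiny_grid)
    cond = geo.build_conductivities(tiny_grid, fibres)
    mus = geo.build_motor_unit_map(tiny_grid, depth_d=0.4, mu1_xt_par=0.4, nmj_xl=0.4)
    return tiny_grid, cond, mus
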