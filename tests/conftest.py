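"""Shared fixtures: small geometries and rheologies used across the suite."""

import numpy as np
import pytest

from coilflow import GeometryParams, RheologyParams, build_geometry, synth_waveform


@pytest.fixture(scope="session")
def default_params():
    # dx = neck_width/12: coarse but resolves the neck well enough for
    # geometry/indices unit tests
    return GeometryParams(grid_nx=104, grid_ny=52, dx=13.0e-3 / 52)


@pytest.fixture(scope="session")
def coarse_geometry(default_params):
    return build_geometry(default_params)


@pytest.fixture(scope="session")
def straight_params():
    return GeometryParams(
        channel_width=4.0e-3,
        channel_length=8.0e-3,
        neck_width=1.0e-3,
        dome1_radius=0.0,
        dome2_radius=0.0,
        grid_nx=64,
        grid_ny=32,
        dx=4.0e-3 / 32,
    )


@pytest.fixture(scope="session")
def straight_geometry(straight_params):
    return build_geometry(straight_params)


@pytest.fixture(scope="session")
def newtonian():
    return RheologyParams(H=0.0, newtonian=True)


@pytest.fixture(scope="session")
def waveform():
    return synth_waveform()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
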