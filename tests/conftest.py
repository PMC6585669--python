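"""Shared fixtures: small geometries and their field solutions.

Session-scoped fixtures cache the expensive raster/field stages; every
fixture is deterministic (fixed seeds).
"""

from __future__ import annotations

import numpy as np
import pytest

from myelinsim import (
    CompartmentProperties,
    EchoGrid,
    FieldConfig,
    GridSpec,
    PackingConfig,
    build_tensor_map,
    circular_mask,
    forward_field,
    make_single_ellipse_axon,
    orientation_map,
    pack_circles,
    rasterize,
)
from myelinsim.geometry import EllipseSpec


@pytest.fixture(scope="session")
def wm_props():
    return CompartmentProperties.literature()


@pytest.fixture(scope="session")
def perp_7t():
    return FieldConfig()  # 7 T, theta = pi/2


@pytest.fixture(scope="session")
def single_axon_map():
    """Nested-circle axon, g = 0.7, well resolved (r_o ~ 143 px)."""
    grid = GridSpec(512, 6.0)
    return make_single_ellipse_axon(EllipseSpec(0.0), 0.7, grid)


@pytest.fixture(scope="session")
def single_axon_field(single_axon_map, wm_props, perp_7t):
    orient = orientation_map(single_axon_map, mode="continuous")
    chi = build_tensor_map(single_axon_map, orient, wm_props)
    return forward_field(chi, perp_7t)


@pytest.fixture(scope="session")
def small_packing():
    """120 gamma-packed circular fibers at 64% fiber density (600 px grid)."""
    return pack_circles(PackingConfig(n_axons=120, seed=3), n_pixels=600)


@pytest.fixture(scope="session")
def small_packed_map(small_packing):
    return rasterize(small_packing)


@pytest.fixture(scope="session")
def small_packed_field(small_packed_map, small_packing, wm_props, perp_7t):
    orient = orientation_map(small_packed_map, small_packing, mode="wedge")
    chi = build_tensor_map(small_packed_map, orient, wm_props)
    return forward_field(chi, perp_7t)


@pytest.fixture(scope="session")
def echoes():
    return EchoGrid.static_preset()


@pytest.fixture
def half_mask(small_packed_map):
    return circular_mask(small_packed_map.grid, 0.5)
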