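"""Shared phantom fixtures.

Phantoms are generated once per session at the coarsest spacing that keeps
the measured quantity inside its validation tolerance; sub-voxel-accuracy
checks (cross-section areas) use the native 0.02 mm study voxel on a short
tube instead of a full-length one.
"""
import numpy as np
import pytest

from airwaykit.phantoms import (MouseAirwayConfig, make_mouse_airway_phantom,
                                make_tilted_tube_mask, make_tube_phantom,
                                make_venturi_phantom)


@pytest.fixture(scope="session")
def tube_005():
    """r = 0.5 mm, L = 10 mm cylinder at 0.05 mm spacing."""
    return make_tube_phantom(0.5, 10.0, 0.05)


@pytest.fixture(scope="session")
def tube_fine():
    """r = 0.5 mm, L = 2 mm cylinder at the native 0.02 mm spacing."""
    return make_tube_phantom(0.5, 2.0, 0.02)


@pytest.fixture(scope="session")
def venturi_004():
    """r 0.8 -> 0.4 mm venturi at 0.04 mm spacing (default section lengths)."""
    return make_venturi_phantom(0.8, 0.4, spacing_mm=0.04)


@pytest.fixture(scope="session")
def mouse_005():
    """Default parametric mouse airway at 0.05 mm spacing."""
    return make_mouse_airway_phantom(MouseAirwayConfig(spacing_mm=0.05), seed=0)


@pytest.fixture(scope="session")
def mouse_scaled_005():
    """Same airway with cross-sections uniformly scaled to 0.8x linear."""
    return make_mouse_airway_phantom(
        MouseAirwayConfig(spacing_mm=0.05, scale_factor=0.8), seed=0
    )


@pytest.fixture(scope="session")
def tilted_cylinder():
    """30-degree oblique cylinder, the analytic oblique-section oracle."""
    return make_tilted_tube_mask(0.5, 3.0, 0.02, 30.0)
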