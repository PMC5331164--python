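"""Shared fixtures: small implant models and material tables.

The ``toy_history`` fixture runs the full default-size design loop once
per session and is shared by every test that inspects its behavior, so
the expensive FE iterations are paid for exactly once.
"""

from __future__ import annotations

import numpy as np
import pytest

from chambergrow import (
    ImplantModelParams,
    RemodelingParams,
    build_synthetic_model,
    default_materials,
    run_design,
)

H = 50e-6  # voxel edge used throughout the tests


@pytest.fixture(scope="session")
def materials():
    return default_materials()


def small_model_params(**overrides) -> ImplantModelParams:
    """An 18x18x28-voxel implant-in-bone model that solves in <1 s."""
    base = dict(
        block_width_x=0.9e-3,
        block_width_y=0.9e-3,
        block_height=1.2e-3,
        cortical_thickness=0.1e-3,
        core_radius=0.15e-3,
        implant_length=1.0e-3,
        abutment_height=0.2e-3,
        thread_pitch=0.3e-3,
        thread_depth=0.1e-3,
        thread_height=0.05e-3,
        thread_offset=0.05e-3,
        trough_depth=0.1e-3,
        roi_margin=0.2e-3,
    )
    base.update(overrides)
    return ImplantModelParams(**base)


@pytest.fixture
def small_params() -> ImplantModelParams:
    return small_model_params()


@pytest.fixture
def small_grid(small_params):
    return build_synthetic_model(small_params)


#: Force (N) that puts the small model's far-field cancellous strain near
#: the middle of the physiological window: E * eps * cross-section.
SMALL_FORCE = 0.69e9 * 750e-6 * (0.9e-3) ** 2


@pytest.fixture(scope="session")
def toy_history():
    """Design history of the default-size model (one run per session)."""
    grid = build_synthetic_model(ImplantModelParams())
    return run_design(
        grid,
        default_materials(),
        3.0,
        RemodelingParams(seed=1),
        max_iter=12,
    )
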