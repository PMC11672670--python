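"""Shared fixtures: toy structures, small mode sets, converged point sets.

The expensive converged kissing-preset distributions (dimensions 2..8,
including the 240-point 8-dimensional set) are computed once per session
and shared between the geometric and the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from nmsphere import (
    MinimizationConfig,
    enm_modes,
    make_toy_structure,
)
from nmsphere.hypersphere import minimize_preset


@pytest.fixture(scope="session")
def toy_uniform():
    """50-bead helix-hinge structure, uniform unit masses."""
    return make_toy_structure(50, kind="helix-hinge", seed=11, mass_pattern="uniform")


@pytest.fixture(scope="session")
def toy_hetero():
    """50-bead helix-hinge structure with heterogeneous (C/N/O) masses."""
    return make_toy_structure(50, kind="helix-hinge", seed=11, mass_pattern="backbone")


@pytest.fixture(scope="session")
def modes_uniform(toy_uniform):
    return enm_modes(toy_uniform, k=8)


@pytest.fixture(scope="session")
def modes_hetero(toy_hetero):
    return enm_modes(toy_hetero, k=8)


# Mdist targets of the optimal kissing configurations: exactly 1 in every
# dimension except D=3, where the icosahedron gives 4/sqrt(10+2*sqrt(5)).
ICOSAHEDRON_MDIST = 4.0 / np.sqrt(10.0 + 2.0 * np.sqrt(5.0))

PRESET_TARGETS = {
    2: 0.9995,
    3: ICOSAHEDRON_MDIST - 5e-4,
    4: 0.9995,
    5: 0.9995,
    6: 0.9995,
    7: 0.9995,
    8: 0.9995,
}


@pytest.fixture(scope="session")
def preset_sets():
    """Converged mirrored kissing-preset distributions for D = 2..8."""
    out = {}
    for dim, target in PRESET_TARGETS.items():
        ps, trace = minimize_preset(
            dim,
            MinimizationConfig(seed=20 + dim),
            restarts=1,
            target_mdist=target,
            max_restarts=20,
        )
        out[dim] = (ps, trace)
    return out
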