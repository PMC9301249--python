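"""Shared fixtures: canonical cells and a seeded synthetic world.

The world and its pipeline run are session-scoped because several test
modules interrogate the same default study conditions (20 × 40 grid,
seed 1, 80-node columns).
"""

from __future__ import annotations

import numpy as np
import pytest

import sedpower as sp
from sedpower.grid_model import Domain, GridCell


def make_cell(**overrides) -> GridCell:
    """A representative shelf cell; override any field."""
    base = dict(
        cell_id="test_cell",
        lon_center=0.0,
        lat_center=0.125,
        resolution=0.25,
        water_depth=100.0,
        sediment_thickness=2000.0,
        quaternary_thickness=2000.0,
        domain=Domain.SHELF,
        sed_rate_holocene=0.05,
        sed_rate_pleistocene=0.045,
        poc0_holocene=0.03,
        poc0_pleistocene=0.03,
        a_holocene=100.0,
        a_pleistocene=120.0,
        nu=0.125,
        phi0=0.6,
        c0=1.5e-3,
        db=10.0,
        opd=0.01,
        smt_depth=5.0,
        b_cells=3e8,
        m_cells=-0.7,
        has_pleistocene=True,
    )
    base.update(overrides)
    return GridCell(**base)


@pytest.fixture(scope="session")
def world():
    return sp.generate_world(sp.WorldConfig(seed=1))


@pytest.fixture(scope="session")
def results(world):
    res = sp.run_world(world)
    assert not res.failures, res.failures
    return res


@pytest.fixture(scope="session")
def depth_table(results):
    return sp.slice_by_depth(results)


@pytest.fixture(scope="session")
def age_table(results):
    return sp.slice_by_age(results)
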