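"""Pipeline driver, horizon slicing, budgets: enumeration oracles and
conservation properties."""

import json

import numpy as np
import pandas as pd
import pytest

import sedpower as sp
from sedpower.aggregation import (
    RunConfig,
    global_budget,
    run_world,
    slice_by_age,
    slice_by_depth,
    write_outputs,
)
from sedpower.grid_model import Domain, GlobalGrid
from sedpower.poc_model import RCMParams, poc_at_age
from sedpower.sediment_column import (
    HOLOCENE_MAX_AGE,
    QUATERNARY_MAX_AGE,
    age_at_depth,
    porosity_at,
)

from conftest import make_cell


def toy_grid() -> GlobalGrid:
    """Three hand-sized columns with explicit areas for enumeration checks."""
    cells = [
        make_cell(
            cell_id="thin",
            sediment_thickness=5.0,
            quaternary_thickness=5.0,
            area_km2=1.0,
            opd=0.02,
            smt_depth=2.0,
        ),
        make_cell(
            cell_id="mid",
            sediment_thickness=50.0,
            quaternary_thickness=50.0,
            area_km2=2.0,
            opd=0.5,
            smt_depth=20.0,
            domain=Domain.MARGIN,
            water_depth=1500.0,
            sed_rate_holocene=0.005,
            sed_rate_pleistocene=0.005,
            poc0_holocene=0.015,
            poc0_pleistocene=0.015,
            a_holocene=5e3,
            a_pleistocene=5e3,
            phi0=0.74,
            c0=1e-3,
            b_cells=1e7,
            m_cells=-0.6,
        ),
        make_cell(
            cell_id="deep",
            sediment_thickness=500.0,
            quaternary_thickness=400.0,
            area_km2=3.0,
            opd=5.0,
            smt_depth=100.0,
            domain=Domain.ABYSS,
            water_depth=4500.0,
            sed_rate_holocene=0.005,
            sed_rate_pleistocene=0.005,
            poc0_holocene=0.005,
            poc0_pleistocene=0.005,
            a_holocene=1e5,
            a_pleistocene=1e5,
            phi0=0.85,
            c0=5e-4,
            b_cells=1e5,
            m_cells=-0.5,
        ),
    ]
    return GlobalGrid(cells=cells, resolution=0.25)


@pytest.fixture(scope="module")
def toy_results():
    return run_world(toy_grid())


def test_depth_horizon_area_enumeration(toy_results):
    table = slice_by_depth(toy_results, [10.0])
    total = table[(table.domain == "total") & (table.zone == "total")].iloc[0]
    # only the 50 m and 500 m columns reach 10 m: 2 + 3 km²
    assert total.area_km2 == pytest.approx(5.0, rel=1e-12)
    assert total.n_cells == 2


def test_depth_horizon_matches_brute_force(toy_results):
    z = 3.0
    table = slice_by_depth(toy_results, [z])
    from sedpower.cells_power import bulk_rate, cell_density, power_per_cell
    from sedpower.poc_model import rpoc_at_age
    from sedpower.zonation import assign_zone

    exp = {}
    for col in toy_results.columns.values():
        c = col.cell
        if c.sediment_thickness < z:
            continue
        age = age_at_depth(c, z)
        params = (
            RCMParams(c.poc0_holocene, c.a_holocene, c.nu)
            if age <= HOLOCENE_MAX_AGE
            else RCMParams(c.poc0_pleistocene, c.a_pleistocene, c.nu)
        )
        phi = porosity_at(z, c.phi0, c.c0)
        zone = assign_zone(z, c.opd, c.smt_depth).value
        key = (c.domain.value, zone)
        rec = exp.setdefault(
            key, {"area": 0.0, "stock": 0.0, "degr": 0.0, "cells": 0.0, "p": []}
        )
        rec["area"] += c.area
        rec["stock"] += poc_at_age(params, age) * (1 - phi) * c.area * 1e10
        rec["degr"] += rpoc_at_age(params, age) * (1 - phi) * c.area * 1e10
        y = cell_density(z, c.b_cells, c.m_cells)
        rec["cells"] += y * c.area * 1e10
        rec["p"].append(
            power_per_cell(
                bulk_rate(rpoc_at_age(params, age), phi),
                toy_results.energies[assign_zone(z, c.opd, c.smt_depth)]["dg_gc"],
                y,
            )
        )
    for (dom, zone), rec in exp.items():
        row = table[(table.domain == dom) & (table.zone == zone)].iloc[0]
        assert row.area_km2 == pytest.approx(rec["area"], rel=1e-12)
        assert row.poc_stock_g == pytest.approx(rec["stock"], rel=1e-12)
        assert row.poc_degradation_g_yr == pytest.approx(rec["degr"], rel=1e-12)
        assert row.cells == pytest.approx(rec["cells"], rel=1e-12)
        assert row.power_median_w == pytest.approx(np.median(rec["p"]), rel=1e-12)


def test_single_contributor_quantiles_collapse(toy_results):
    table = slice_by_depth(toy_results, [100.0])  # only the 500 m column
    row = table[(table.domain == "total") & (table.zone == "total")].iloc[0]
    assert row.n_cells == 1
    assert row.power_q25_w == row.power_median_w == row.power_q75_w


def test_partitions_sum_to_totals(depth_table, age_table):
    for table in (depth_table, age_table):
        for col in ("area_km2", "poc_stock_g", "cells", "poc_degradation_g_yr"):
            for (kind, hv), sub in table.groupby(["horizon_kind", "horizon_value"]):
                parts = sub[(sub.domain != "total") & (sub.zone != "total")][col].sum()
                total = sub[(sub.domain == "total") & (sub.zone == "total")][col].iloc[0]
                assert parts == pytest.approx(total, rel=1e-9, abs=1e-30)


def test_empty_horizon_is_zeros(toy_results):
    table = slice_by_depth(toy_results, [1000.0])
    total = table[(table.domain == "total") & (table.zone == "total")].iloc[0]
    assert total.area_km2 == 0.0 and total.n_cells == 0
    assert np.isnan(total.power_median_w)


def test_age_zero_includes_all_cells(toy_results):
    table = slice_by_age(toy_results, [0.0])
    total = table[(table.domain == "total") & (table.zone == "total")].iloc[0]
    assert total.area_km2 == pytest.approx(6.0, rel=1e-12)


def test_age_beyond_quaternary_rejected(toy_results):
    with pytest.raises(ValueError):
        slice_by_age(toy_results, [3e6])


def test_gap_halves_shelf_area_across_boundary():
    cfg = sp.WorldConfig(seed=3, pleistocene_gap_fraction=0.5)
    res = run_world(sp.generate_world(cfg))
    table = slice_by_age(res, [1e4, 2e4])
    shelf = table[(table.domain == "shelf") & (table.zone == "total")]
    young = shelf[shelf.horizon_value == 1e4].area_km2.iloc[0]
    old = shelf[shelf.horizon_value == 2e4].area_km2.iloc[0]
    assert old / young == pytest.approx(0.5, abs=0.2)


def test_budget_matches_brute_force(toy_results):
    budget = global_budget(toy_results)
    # independent single-pass enumeration over all mesh intervals
    vol = {}
    cells = {}
    for col in toy_results.columns.values():
        mesh, c = col.mesh, col.cell
        widths = mesh.interval_widths()
        for i in range(mesh.n_intervals):
            zn = mesh.zone[i].value
            vol[zn] = vol.get(zn, 0.0) + c.area * widths[i] / 1000.0
            mean_y = 0.5 * (col.y[i] + col.y[i + 1])
            cells[zn] = cells.get(zn, 0.0) + mean_y * c.area * 1e10 * widths[i] * 100.0
    for zn, v in vol.items():
        assert budget.volume_km3_by_zone[zn] == pytest.approx(v, rel=1e-12)
    for zn, v in cells.items():
        assert budget.cells_by_zone[zn] == pytest.approx(v, rel=1e-12)


def test_budget_percentages_close(results):
    budget = global_budget(results)
    for pct in (
        budget.volume_pct_by_zone,
        budget.poc_stock_pct_by_domain,
        budget.poc_degradation_pct_by_zone,
        budget.cells_pct_by_zone,
        budget.quaternary_cells_pct_by_zone,
    ):
        assert sum(pct.values()) == pytest.approx(100.0, abs=1e-6)


def test_zero_thickness_cell_contributes_nothing():
    import warnings

    cells = [
        make_cell(cell_id="ok", area_km2=1.0),
        make_cell(
            cell_id="empty",
            sediment_thickness=0.0,
            quaternary_thickness=0.0,
            area_km2=1.0,
        ),
    ]
    grid = GlobalGrid(cells=cells, resolution=0.25)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = run_world(grid)
    budget = global_budget(res)
    only = run_world(GlobalGrid(cells=[cells[0]], resolution=0.25))
    budget_only = global_budget(only)
    assert sum(budget.volume_km3_by_zone.values()) == pytest.approx(
        sum(budget_only.volume_km3_by_zone.values()), rel=1e-12
    )


def test_order_independence(world):
    res_fwd = run_world(world)
    shuffled = GlobalGrid(
        cells=list(reversed(world.cells)),
        resolution=world.resolution,
        seed=world.seed,
    )
    res_rev = run_world(shuffled)
    t1 = slice_by_depth(res_fwd, [1.0, 100.0])
    t2 = slice_by_depth(res_rev, [1.0, 100.0])
    pd.testing.assert_frame_equal(t1, t2)


def test_two_way_integration_consistency(world):
    """Quaternary POC stock per cell: depth-wise vs age-wise integration."""
    total_depth = 0.0
    total_age = 0.0
    for cell in list(world)[:40]:
        zq = min(cell.quaternary_thickness, cell.sediment_thickness)
        zs = np.linspace(0, zq, 4000)
        ages = age_at_depth(cell, zs)
        poc = np.where(
            ages <= HOLOCENE_MAX_AGE,
            poc_at_age(RCMParams(cell.poc0_holocene, cell.a_holocene, cell.nu), ages),
            poc_at_age(
                RCMParams(cell.poc0_pleistocene, cell.a_pleistocene, cell.nu), ages
            ),
        )
        if not cell.has_pleistocene:
            poc = np.where(ages <= HOLOCENE_MAX_AGE, poc, 0.0)
        phi = porosity_at(zs, cell.phi0, cell.c0)
        route_a = np.trapezoid(poc * (1 - phi), zs) * 100.0  # per cm² column
        t_base = float(age_at_depth(cell, zq))
        t_max = min(QUATERNARY_MAX_AGE, t_base)
        if not cell.has_pleistocene:
            t_max = min(t_max, HOLOCENE_MAX_AGE)
        ts = np.linspace(0, t_max, 4000)
        poc_t = np.where(
            ts <= HOLOCENE_MAX_AGE,
            poc_at_age(RCMParams(cell.poc0_holocene, cell.a_holocene, cell.nu), ts),
            poc_at_age(
                RCMParams(cell.poc0_pleistocene, cell.a_pleistocene, cell.nu), ts
            ),
        )
        omega_m = np.where(
            ts <= HOLOCENE_MAX_AGE,
            cell.sed_rate_holocene,
            cell.sed_rate_pleistocene,
        ) / 100.0
        # dz_solid/dt = (1-Φ₀) ω; POC is per dry volume, so the age-route
        # integrand needs no porosity factor beyond the solid flux
        route_b = np.trapezoid(poc_t * (1 - cell.phi0) * omega_m, ts) * 100.0
        total_depth += route_a * cell.area
        total_age += route_b * cell.area
    assert total_age == pytest.approx(total_depth, rel=0.01)


def test_write_outputs_and_manifest(results, tmp_path):
    write_outputs(results, tmp_path)
    assert (tmp_path / "horizons_depth.csv").exists()
    assert (tmp_path / "horizons_age.csv").exists()
    manifest = json.loads((tmp_path / "run_manifest.json").read_text())
    assert manifest["grid_seed"] == 1
    assert "zone_energies" in manifest and "oxic" in manifest["zone_energies"]
    budget = json.loads((tmp_path / "global_budget.json").read_text())
    assert sum(budget["volume_pct_by_zone"].values()) == pytest.approx(100.0, abs=1e-6)


def test_failures_recorded_without_abort(world):
    good = make_cell(cell_id="good", area_km2=1.0)
    bad = make_cell(cell_id="bad", area_km2=1.0)
    bad.phi0 = float("nan")  # corrupt after construction to provoke a failure
    grid = GlobalGrid(cells=[good, bad], resolution=0.25)
    res = run_world(grid)
    assert "bad" in res.failures
    assert "good" in res.columns
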