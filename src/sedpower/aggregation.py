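"""Global pipeline driver and horizon/budget summaries.

``run_world`` evaluates every column of a grid (mesh, POC profile, zones,
cell abundance, per-cell power) and returns a results store.  Summaries
slice the world along horizons of equal sediment depth or equal burial age
— the two do not coincide, because burial rate varies by orders of
magnitude across the seafloor — and integrate global budgets (sediment
volume and cells by catabolic zone from seafloor to basement; POC stored
and degraded over the Quaternary section only).

Horizon quantities are evaluated exactly from the closed-form column models
at the horizon depth (the production path is analytic, so no mesh
interpolation is needed); column-integrated budgets use the mesh intervals,
whose edges include every epoch and zone boundary.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .bioenergetics import default_contexts, default_reactions, zone_energies
from .cells_power import bulk_rate, cell_density, power_per_cell
from .grid_model import Domain, GlobalGrid, GridCell
from .poc_model import PocProfile, column_poc, poc_at_age, rpoc_at_age, _epoch_params
from .sediment_column import (
    HOLOCENE_MAX_AGE,
    QUATERNARY_MAX_AGE,
    ColumnMesh,
    Epoch,
    MeshConfig,
    age_at_depth,
    build_mesh,
    depth_of_age,
    porosity_at,
)
from .zonation import Zone, assign_zone, effective_smt, zone_volumes

__all__ = [
    "RunConfig",
    "WorldResults",
    "GlobalBudget",
    "run_world",
    "slice_by_depth",
    "slice_by_age",
    "global_budget",
    "power_quantiles",
    "default_depth_horizons",
    "default_age_horizons",
]

TOTAL = "total"  # marginal label in summary tables


def default_depth_horizons() -> np.ndarray:
    """25 log-spaced depth horizons, 0.1 to 10,000 mbsf."""
    return np.geomspace(0.1, 10_000.0, 25)


def default_age_horizons() -> np.ndarray:
    """25 log-spaced age horizons, 1 kyr to 2.59 Myr."""
    return np.geomspace(1.0e3, QUATERNARY_MAX_AGE, 25)


@dataclass
class RunConfig:
    """Pipeline settings (mesh, horizons, quantile weighting)."""

    mesh: MeshConfig = field(default_factory=MeshConfig)
    depth_horizons: list[float] = field(
        default_factory=lambda: list(default_depth_horizons())
    )
    age_horizons: list[float] = field(
        default_factory=lambda: list(default_age_horizons())
    )
    area_weighted_quantiles: bool = False

    def validate(self) -> None:
        self.mesh.validate()
        for name in ("depth_horizons", "age_horizons"):
            vals = np.asarray(getattr(self, name), dtype=float)
            if len(vals) and (np.any(vals <= 0) or np.any(np.diff(vals) <= 0)):
                raise ValueError(f"{name} must be positive and strictly ascending")
        if np.any(np.asarray(self.age_horizons) > QUATERNARY_MAX_AGE + 1e-6):
            raise ValueError("age horizons beyond the Quaternary are not supported")


@dataclass
class CellColumn:
    """Per-cell column results (mesh plus nodal profiles)."""

    cell: GridCell
    mesh: ColumnMesh
    poc: PocProfile
    y: np.ndarray  # cells per bulk cm^3 at nodes
    power: np.ndarray  # W per cell at nodes; NaN outside the Quaternary


@dataclass
class WorldResults:
    """Results store for one pipeline run."""

    grid: GlobalGrid
    config: RunConfig
    energies: dict  # Zone -> {dg_mol, dg_gc, q}
    columns: dict  # cell_id -> CellColumn
    failures: dict  # cell_id -> error message

    @property
    def ok(self) -> bool:
        return not self.failures


def _node_powers(cell: GridCell, mesh: ColumnMesh, profile: PocProfile, energies):
    """Per-node abundance and power for one column."""
    if len(mesh) == 0:
        return np.array([]), np.array([])
    z = np.maximum(mesh.depths, 1e-6)
    y = cell_density(z, cell.b_cells, cell.m_cells)
    r = bulk_rate(profile.rpoc, mesh.porosity)
    smt = effective_smt(cell.smt_depth, cell.sediment_thickness)
    power = np.empty(len(mesh))
    for i, (zi, ri, yi) in enumerate(zip(mesh.depths, r, y)):
        if mesh.epoch[i] is Epoch.PRE_QUATERNARY:
            power[i] = np.nan
            continue
        zone = assign_zone(zi, cell.opd, smt)
        power[i] = power_per_cell(ri, energies[zone]["dg_gc"], yi)
    return y, power


def run_world(
    grid: GlobalGrid,
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
) -> WorldResults:
    """Run every column of a grid; deterministic for fixed grid and config.

    Cell failures are recorded and the run continues; callers inspect
    ``results.failures`` (the CLI exits nonzero if any).  With ``outdir``
    set, a run manifest plus the summary tables and budget are written.
    """
    config = config or RunConfig()
    config.validate()
    energies = zone_energies(default_reactions(), default_contexts())
    columns: dict = {}
    failures: dict = {}
    for cell in sorted(grid.cells, key=lambda c: c.cell_id):
        try:
            mesh = build_mesh(cell, config.mesh)
            profile = column_poc(cell, mesh)
            y, power = _node_powers(cell, mesh, profile, energies)
            columns[cell.cell_id] = CellColumn(
                cell=cell, mesh=mesh, poc=profile, y=y, power=power
            )
        except Exception as exc:  # noqa: BLE001 - per-cell fault isolation
            failures[cell.cell_id] = f"{type(exc).__name__}: {exc}"
    results = WorldResults(
        grid=grid, config=config, energies=energies, columns=columns, failures=failures
    )
    if outdir is not None:
        write_outputs(results, outdir)
    return results


# ----------------------------------------------------------------- horizons


def _eval_cell_at_depth(cell: GridCell, z: float, energies) -> dict | None:
    """Closed-form column state of one cell at depth ``z`` (m).

    Returns None if the cell has no sediment at that depth.
    """
    if z > cell.sediment_thickness:
        return None
    age = age_at_depth(cell, z)
    smt = effective_smt(cell.smt_depth, cell.sediment_thickness)
    zone = assign_zone(z, cell.opd, smt)
    in_quaternary = (
        z <= min(cell.quaternary_thickness, cell.sediment_thickness) + 1e-12
        and age <= QUATERNARY_MAX_AGE
        and (cell.has_pleistocene or age <= HOLOCENE_MAX_AGE)
    )
    phi = porosity_at(z, cell.phi0, cell.c0)
    y = cell_density(max(z, 1e-6), cell.b_cells, cell.m_cells)
    if in_quaternary:
        epoch = Epoch.HOLOCENE if age <= HOLOCENE_MAX_AGE else Epoch.PLEISTOCENE
        params = _epoch_params(cell, epoch)
        poc = poc_at_age(params, age)
        rp = rpoc_at_age(params, age)
        power = power_per_cell(bulk_rate(rp, phi), energies[zone]["dg_gc"], y)
    else:
        poc, rp, power = 0.0, 0.0, np.nan
    area_cm2 = cell.area * 1e10
    return {
        "cell_id": cell.cell_id,
        "domain": cell.domain.value,
        "zone": zone.value,
        "area_km2": cell.area,
        # per-1-cm-thick slab of this cell at the horizon
        "poc_stock_g": poc * (1.0 - phi) * area_cm2 * 1.0,
        "poc_degradation_g_yr": rp * (1.0 - phi) * area_cm2 * 1.0,
        "cells": y * area_cm2 * 1.0,
        "power_w": power,
    }


def _weighted_quantiles(values: np.ndarray, weights: np.ndarray, qs) -> list[float]:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= np.sum(w)
    return [float(np.interp(q, cum, v)) for q in qs]


def _quantiles(sub: pd.DataFrame, weighted: bool) -> tuple[float, float, float]:
    vals = sub["power_w"].to_numpy(dtype=float)
    mask = np.isfinite(vals)
    if not mask.any():
        return (np.nan, np.nan, np.nan)
    vals = vals[mask]
    if weighted:
        w = sub["area_km2"].to_numpy(dtype=float)[mask]
        q25, q50, q75 = _weighted_quantiles(vals, w, (0.25, 0.5, 0.75))
    else:
        q25, q50, q75 = np.percentile(vals, [25, 50, 75])
    return float(q25), float(q50), float(q75)


_SUM_COLS = ["area_km2", "poc_stock_g", "poc_degradation_g_yr", "cells"]


def _summarize_horizon(
    records: pd.DataFrame, kind: str, value: float, weighted: bool
) -> pd.DataFrame:
    """Aggregate per-cell horizon records into tidy (domain × zone) rows,
    including ``total`` marginals."""
    rows = []
    domains = [d.value for d in Domain] + [TOTAL]
    zones = [z.value for z in Zone] + [TOTAL]
    for dom in domains:
        dsub = records if dom == TOTAL else records[records["domain"] == dom]
        for zn in zones:
            sub = dsub if zn == TOTAL else dsub[dsub["zone"] == zn]
            row = {
                "horizon_kind": kind,
                "horizon_value": value,
                "domain": dom,
                "zone": zn,
                "n_cells": len(sub),
            }
            for col in _SUM_COLS:
                row[col] = float(sub[col].sum()) if len(sub) else 0.0
            q25, q50, q75 = (
                _quantiles(sub, weighted) if len(sub) else (np.nan, np.nan, np.nan)
            )
            row["power_q25_w"], row["power_median_w"], row["power_q75_w"] = (
                q25,
                q50,
                q75,
            )
            rows.append(row)
    return pd.DataFrame(rows)


_EMPTY_RECORDS = pd.DataFrame(
    columns=["cell_id", "domain", "zone"] + _SUM_COLS + ["power_w"]
)


def slice_by_depth(results: WorldResults, depths=None) -> pd.DataFrame:
    """Horizon summaries at fixed depths below seafloor (tidy DataFrame)."""
    depths = (
        np.asarray(results.config.depth_horizons, dtype=float)
        if depths is None
        else np.asarray(depths, dtype=float)
    )
    if np.any(depths <= 0) or np.any(np.diff(depths) <= 0):
        raise ValueError("depth horizons must be positive ascending")
    frames = []
    for z in depths:
        recs = [
            r
            for col in results.columns.values()
            if (r := _eval_cell_at_depth(col.cell, float(z), results.energies))
            is not None
        ]
        df = pd.DataFrame(recs) if recs else _EMPTY_RECORDS
        frames.append(
            _summarize_horizon(
                df, "depth", float(z), results.config.area_weighted_quantiles
            )
        )
    return pd.concat(frames, ignore_index=True)


def slice_by_age(results: WorldResults, ages=None) -> pd.DataFrame:
    """Horizon summaries at fixed burial ages (tidy DataFrame).

    Cells lacking sediment of a given age (thin or Pleistocene-free
    columns) are excluded from that horizon.
    """
    ages = (
        np.asarray(results.config.age_horizons, dtype=float)
        if ages is None
        else np.asarray(ages, dtype=float)
    )
    if np.any(ages < 0) or np.any(np.diff(ages) <= 0):
        raise ValueError("age horizons must be non-negative ascending")
    if np.any(ages > QUATERNARY_MAX_AGE + 1e-6):
        raise ValueError("age horizons beyond 2.59 Myr are out of model scope")
    frames = []
    for t in ages:
        recs = []
        for col in results.columns.values():
            z_t = depth_of_age(float(t), col.cell)
            if np.isnan(z_t):
                continue
            rec = _eval_cell_at_depth(col.cell, z_t, results.energies)
            if rec is not None:
                recs.append(rec)
        df = pd.DataFrame(recs) if recs else _EMPTY_RECORDS
        frames.append(
            _summarize_horizon(
                df, "age", float(t), results.config.area_weighted_quantiles
            )
        )
    return pd.concat(frames, ignore_index=True)


def power_quantiles(
    results: WorldResults, horizon_kind: str, horizon_value: float
) -> pd.DataFrame:
    """(q25, median, q75) of per-cell power per domain × zone at one horizon."""
    if horizon_kind == "depth":
        table = slice_by_depth(results, [horizon_value])
    elif horizon_kind == "age":
        table = slice_by_age(results, [horizon_value])
    else:
        raise ValueError("horizon_kind must be 'depth' or 'age'")
    cols = [
        "domain",
        "zone",
        "n_cells",
        "power_q25_w",
        "power_median_w",
        "power_q75_w",
    ]
    return table[cols].copy()


# ------------------------------------------------------------------- budget


@dataclass
class GlobalBudget:
    """Column-integrated world totals and their percentage partitions."""

    volume_km3_by_zone: dict
    volume_pct_by_zone: dict
    quaternary_volume_km3_by_zone: dict
    quaternary_volume_pct_by_zone: dict
    poc_stock_g_by_domain: dict  # Quaternary only
    poc_stock_pct_by_domain: dict
    poc_degradation_g_yr_by_zone: dict  # Quaternary only, by pathway
    poc_degradation_pct_by_zone: dict
    cells_by_zone: dict  # SWI to basement
    cells_pct_by_zone: dict
    quaternary_cells_by_zone: dict
    quaternary_cells_pct_by_zone: dict
    total_area_km2: float = 0.0

    def to_dict(self) -> dict:
        return asdict(self)


def _pct(d: dict) -> dict:
    total = sum(d.values())
    if total <= 0:
        return {k: 0.0 for k in d}
    return {k: 100.0 * v / total for k, v in d.items()}


def _interval_trapz(values: np.ndarray, widths_m: np.ndarray) -> np.ndarray:
    """Trapezoid integral of a nodal quantity over each mesh interval."""
    return 0.5 * (values[1:] + values[:-1]) * widths_m


def global_budget(results: WorldResults) -> GlobalBudget:
    """Brute-force-checkable global totals from the per-cell columns."""
    zones = list(Zone)
    vol = {z.value: 0.0 for z in zones}
    vol_q = {z.value: 0.0 for z in zones}
    cells = {z.value: 0.0 for z in zones}
    cells_q = {z.value: 0.0 for z in zones}
    degr = {z.value: 0.0 for z in zones}
    stock = {d.value: 0.0 for d in Domain}
    for col in results.columns.values():
        cell, mesh = col.cell, col.mesh
        if len(mesh) < 2:
            continue
        zv = zone_volumes(cell, mesh)["bulk"]
        for z in zones:
            vol[z.value] += zv[z]
        widths = mesh.interval_widths()
        izones = mesh.interval_zones()
        iepochs = mesh.interval_epochs()
        quaternary = np.array(
            [e is not Epoch.PRE_QUATERNARY for e in iepochs], dtype=bool
        )
        area_cm2 = cell.area * 1e10
        # cm^3 of bulk sediment per interval: area_cm2 * width_m * 100
        vol_cm3 = area_cm2 * widths * 100.0
        cells_per = _interval_trapz(col.y, widths) / np.maximum(widths, 1e-300)
        # note: cells_per is the interval-mean density; volume factor below
        solid_frac = 0.5 * (
            (1.0 - mesh.porosity[1:]) + (1.0 - mesh.porosity[:-1])
        )
        poc_mean = 0.5 * (col.poc.poc[1:] + col.poc.poc[:-1])
        rpoc_mean = 0.5 * (col.poc.rpoc[1:] + col.poc.rpoc[:-1])
        for i in range(len(widths)):
            zname = izones[i].value
            cells_i = cells_per[i] * vol_cm3[i]
            cells[zname] += cells_i
            if quaternary[i]:
                vol_q[zname] += cell.area * widths[i] / 1000.0
                cells_q[zname] += cells_i
                degr[zname] += rpoc_mean[i] * solid_frac[i] * vol_cm3[i]
                stock[cell.domain.value] += poc_mean[i] * solid_frac[i] * vol_cm3[i]
    return GlobalBudget(
        volume_km3_by_zone=vol,
        volume_pct_by_zone=_pct(vol),
        quaternary_volume_km3_by_zone=vol_q,
        quaternary_volume_pct_by_zone=_pct(vol_q),
        poc_stock_g_by_domain=stock,
        poc_stock_pct_by_domain=_pct(stock),
        poc_degradation_g_yr_by_zone=degr,
        poc_degradation_pct_by_zone=_pct(degr),
        cells_by_zone=cells,
        cells_pct_by_zone=_pct(cells),
        quaternary_cells_by_zone=cells_q,
        quaternary_cells_pct_by_zone=_pct(cells_q),
        total_area_km2=results.grid.total_area(),
    )


# ------------------------------------------------------------------ outputs


def write_outputs(results: WorldResults, outdir: str | Path) -> None:
    """Write manifest, horizon tables and the global budget to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "sedpower",
        "version": _pkg_version,
        "grid_seed": results.grid.seed,
        "grid_provenance": results.grid.provenance,
        "n_cells": len(results.grid),
        "config": {
            "mesh": asdict(results.config.mesh),
            "depth_horizons": list(map(float, results.config.depth_horizons)),
            "age_horizons": list(map(float, results.config.age_horizons)),
            "area_weighted_quantiles": results.config.area_weighted_quantiles,
        },
        "zone_energies": {z.value: v for z, v in results.energies.items()},
        "failures": results.failures,
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    slice_by_depth(results).to_csv(
        outdir / "horizons_depth.csv", index=False, float_format="%.12g"
    )
    slice_by_age(results).to_csv(
        outdir / "horizons_age.csv", index=False, float_format="%.12g"
    )
    budget = global_budget(results)
    (outdir / "global_budget.json").write_text(json.dumps(budget.to_dict(), indent=2))


def export_profile_csv(col: CellColumn, path: str | Path) -> None:
    """Dump one cell's column profile (debugging aid)."""
    df = pd.DataFrame(
        {
            "depth_m": col.mesh.depths,
            "porosity": col.mesh.porosity,
            "age_yr": col.mesh.age,
            "epoch": [e.value for e in col.mesh.epoch],
            "zone": [z.value for z in col.mesh.zone],
            "poc_gc_cm3": col.poc.poc,
            "rpoc_gc_cm3_yr": col.poc.rpoc,
            "burial_flux_gc_cm2_yr": col.poc.burial_flux,
            "cells_cm3": col.y,
            "power_w_cell": col.power,
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")
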