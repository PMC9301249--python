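"""Global seafloor grid: cells, depositional domains, geometry and I/O.

The analysis runs on a regular lon/lat grid of seafloor cells.  Each cell
carries the forcing fields the column models need: water depth, sediment and
Quaternary thickness, epoch-specific sedimentation rates and organic-carbon
boundary conditions, porosity parameters, bioturbation coefficient, redox
boundary depths (oxygen penetration depth and sulfate-methane transition) and
the parameters of the cell-abundance power law.

Cells are classified into three depositional domains by water depth:
``shelf`` (< 200 m, or < 500 m in the Antarctic band), ``abyss`` (> 3500 m)
and ``margin`` in between.  Cell areas are spherical-zone areas on an
authalic sphere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "Domain",
    "GridCell",
    "GlobalGrid",
    "classify_domain",
    "cell_area",
    "EARTH_RADIUS_KM",
    "ANTARCTIC_LAT_CUTOFF",
]

EARTH_RADIUS_KM = 6371.0
ANTARCTIC_LAT_CUTOFF = -60.0

#: water-depth limits (m) of the shelf and margin domains
SHELF_MAX_DEPTH = 200.0
ANTARCTIC_SHELF_MAX_DEPTH = 500.0
MARGIN_MAX_DEPTH = 3500.0


class Domain(str, Enum):
    """Depositional setting of a seafloor cell."""

    SHELF = "shelf"
    MARGIN = "margin"
    ABYSS = "abyss"


def classify_domain(
    water_depth: float,
    lat: float,
    antarctic_lat_cutoff: float = ANTARCTIC_LAT_CUTOFF,
) -> Domain:
    """Classify a submerged cell into shelf / margin / abyss by water depth.

    Shelf is shallower than 200 m, except poleward of the Antarctic cutoff
    latitude where the shelf break sits near 500 m.  Abyssal plain is deeper
    than 3500 m; everything in between is continental margin.

    Parameters
    ----------
    water_depth:
        Water column height above the cell, m (> 0 means submerged).
    lat:
        Latitude of the cell center, degrees.
    antarctic_lat_cutoff:
        Latitudes at or below this value use the deeper Antarctic shelf break.
    """
    if not water_depth > 0:
        raise ValueError(f"water_depth must be positive, got {water_depth}")
    shelf_break = (
        ANTARCTIC_SHELF_MAX_DEPTH if lat <= antarctic_lat_cutoff else SHELF_MAX_DEPTH
    )
    if water_depth < shelf_break:
        return Domain.SHELF
    if water_depth > MARGIN_MAX_DEPTH:
        return Domain.ABYSS
    return Domain.MARGIN


def cell_area(
    lat_center: float, resolution: float, earth_radius: float = EARTH_RADIUS_KM
) -> float:
    """Spherical-zone area (km²) of a square lon/lat cell.

    ``A = R² Δλ (sin φ_top − sin φ_bot)`` with Δλ the longitudinal width in
    radians.  Latitude bands are taken closed at the bottom edge, open at the
    top; the cell must not extend past a pole.
    """
    if resolution <= 0:
        raise ValueError(f"resolution must be positive, got {resolution}")
    half = resolution / 2.0
    if abs(lat_center) + half > 90.0 + 1e-12:
        raise ValueError(
            f"cell at lat {lat_center} with resolution {resolution} crosses a pole"
        )
    lat_bot = math.radians(lat_center - half)
    lat_top = math.radians(lat_center + half)
    dlon = math.radians(resolution)
    return earth_radius**2 * dlon * (math.sin(lat_top) - math.sin(lat_bot))


@dataclass
class GridCell:
    """One seafloor grid cell with all per-cell forcings and parameters.

    Units: depths/thicknesses m; sedimentation rates cm yr⁻¹; POC boundary
    concentrations g C per cm³ dry sediment; ``a`` yr; ``c0`` m⁻¹; ``db``
    cm² yr⁻¹; ``b_cells`` cells cm⁻³ (abundance at 1 mbsf).
    """

    cell_id: str
    lon_center: float
    lat_center: float
    resolution: float
    water_depth: float
    sediment_thickness: float
    quaternary_thickness: float
    domain: Domain
    sed_rate_holocene: float
    sed_rate_pleistocene: float
    poc0_holocene: float
    poc0_pleistocene: float
    a_holocene: float
    a_pleistocene: float
    nu: float
    phi0: float
    c0: float
    db: float
    opd: float
    smt_depth: float
    b_cells: float
    m_cells: float
    has_pleistocene: bool = True
    #: optional explicit area override (km²); computed from geometry if None
    area_km2: float | None = None

    def __post_init__(self) -> None:
        self.domain = Domain(self.domain)
        # opd/smt consistency is enforced by clamping rather than rejection:
        # the redox compilations the fields emulate are independent and may
        # disagree by small amounts.
        if np.isfinite(self.smt_depth) and self.opd > self.smt_depth:
            self.opd = self.smt_depth
        self.validate()

    def validate(self) -> None:
        if not self.water_depth > 0:
            raise ValueError(f"{self.cell_id}: water_depth must be > 0")
        if not 0 < self.phi0 < 1:
            raise ValueError(f"{self.cell_id}: phi0 must lie in (0, 1)")
        if not self.c0 > 0:
            raise ValueError(f"{self.cell_id}: c0 must be > 0")
        if not self.sediment_thickness >= self.quaternary_thickness >= 0:
            raise ValueError(
                f"{self.cell_id}: need sediment_thickness >= quaternary_thickness >= 0"
            )
        if not (self.sed_rate_holocene > 0 and self.sed_rate_pleistocene > 0):
            raise ValueError(f"{self.cell_id}: sedimentation rates must be > 0")
        if self.poc0_holocene < 0 or self.poc0_pleistocene < 0:
            raise ValueError(f"{self.cell_id}: poc0 must be >= 0")
        if not (self.a_holocene > 0 and self.a_pleistocene > 0):
            raise ValueError(f"{self.cell_id}: a parameters must be > 0")
        if not 0 < self.nu < 1:
            raise ValueError(f"{self.cell_id}: nu must lie in (0, 1)")
        if self.db < 0:
            raise ValueError(f"{self.cell_id}: db must be >= 0")
        if not self.opd >= 0:
            raise ValueError(f"{self.cell_id}: opd must be >= 0")
        if np.isfinite(self.smt_depth) and self.opd > self.smt_depth:
            raise ValueError(f"{self.cell_id}: opd must not exceed smt_depth")
        if not self.b_cells > 0:
            raise ValueError(f"{self.cell_id}: b_cells must be > 0")

    @property
    def area(self) -> float:
        """Cell area in km² (explicit override, else spherical zone)."""
        if self.area_km2 is not None and np.isfinite(self.area_km2):
            return float(self.area_km2)
        return cell_area(self.lat_center, self.resolution)


_FIELD_NAMES = [f.name for f in fields(GridCell)]


@dataclass
class GlobalGrid:
    """Ordered collection of grid cells plus provenance metadata."""

    cells: list[GridCell]
    resolution: float
    seed: int | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [c.cell_id for c in self.cells]
        if len(set(ids)) != len(ids):
            raise ValueError("cell_ids must be unique")
        for c in self.cells:
            if abs(c.resolution - self.resolution) > 1e-9:
                raise ValueError("all cells must share the grid resolution")

    def __len__(self) -> int:
        return len(self.cells)

    def __iter__(self) -> Iterator[GridCell]:
        return iter(self.cells)

    def total_area(self) -> float:
        """Total seafloor area of the grid, km²."""
        return float(sum(c.area for c in self.cells))

    # ------------------------------------------------------------------ I/O
    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            row = {name: getattr(c, name) for name in _FIELD_NAMES}
            row["domain"] = c.domain.value
            rows.append(row)
        return pd.DataFrame(rows, columns=_FIELD_NAMES)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        resolution: float | None = None,
        seed: int | None = None,
        provenance: str = "",
    ) -> "GlobalGrid":
        cells = []
        for rec in df.to_dict("records"):
            kwargs = {name: rec[name] for name in _FIELD_NAMES if name in rec}
            if "area_km2" in kwargs and pd.isna(kwargs["area_km2"]):
                kwargs["area_km2"] = None
            kwargs["has_pleistocene"] = bool(kwargs["has_pleistocene"])
            kwargs["cell_id"] = str(kwargs["cell_id"])
            cells.append(GridCell(**kwargs))
        if resolution is None:
            resolution = cells[0].resolution if cells else 1.0
        return cls(cells=cells, resolution=resolution, seed=seed, provenance=provenance)

    def to_csv(self, path: str | Path) -> None:
        """Write one row per cell; floats at full round-trip precision."""
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path, **kw) -> "GlobalGrid":
        return cls.from_dataframe(pd.read_csv(path), **kw)

    def to_netcdf(self, path: str | Path) -> None:
        """Write the grid as a lat × lon NetCDF-3 file (scipy backend)."""
        df = self.to_dataframe()
        lats = np.sort(df["lat_center"].unique())
        lons = np.sort(df["lon_center"].unique())
        ds = xr.Dataset(coords={"lat": lats, "lon": lons})
        idx = df.set_index(["lat_center", "lon_center"])
        for name in _FIELD_NAMES:
            if name in ("lat_center", "lon_center"):
                continue
            col = idx[name]
            if name == "domain":
                col = col.map(lambda d: list(Domain).index(Domain(d)))
            elif name == "has_pleistocene":
                col = col.astype(int)
            elif name == "cell_id":
                # NetCDF-3 has no string type beyond char arrays; cell ids are
                # reconstructed from coordinates on read.
                continue
            arr = (
                col.astype(float)
                .reindex(pd.MultiIndex.from_product([lats, lons]))
                .to_numpy()
                .reshape(len(lats), len(lons))
            )
            ds[name] = (("lat", "lon"), arr)
        ds.attrs["resolution"] = self.resolution
        ds.attrs["seed"] = -1 if self.seed is None else int(self.seed)
        ds.attrs["provenance"] = self.provenance
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path: str | Path) -> "GlobalGrid":
        with xr.open_dataset(path, engine="scipy") as ds:
            ds = ds.load()
        cells = []
        lats = ds["lat"].values
        lons = ds["lon"].values
        for i, lat in enumerate(lats):
            for j, lon in enumerate(lons):
                if np.isnan(float(ds["water_depth"][i, j])):
                    continue
                kwargs: dict = {"lat_center": float(lat), "lon_center": float(lon)}
                for name in _FIELD_NAMES:
                    if name in ("lat_center", "lon_center", "cell_id"):
                        continue
                    val = float(ds[name][i, j])
                    if name == "domain":
                        kwargs[name] = list(Domain)[int(round(val))]
                    elif name == "has_pleistocene":
                        kwargs[name] = bool(round(val))
                    elif name == "area_km2":
                        kwargs[name] = None if np.isnan(val) else val
                    else:
                        kwargs[name] = val
                kwargs["cell_id"] = cell_id_for(float(lat), float(lon))
                cells.append(GridCell(**kwargs))
        seed = int(ds.attrs.get("seed", -1))
        return cls(
            cells=cells,
            resolution=float(ds.attrs["resolution"]),
            seed=None if seed < 0 else seed,
            provenance=str(ds.attrs.get("provenance", "")),
        )


def cell_id_for(lat: float, lon: float) -> str:
    """Canonical cell id from center coordinates."""
    return f"c_{lat:+08.3f}_{lon:+08.3f}"
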