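"""Vertical sediment column: porosity, burial age, epoch layering, mesh.

Porosity follows steady-state compaction, ``Φ(z) = Φ₀ exp(−c₀ z)``.  Burial
age at depth derives from conservation of the solid-volume flux
``(1 − Φ(z)) ω(z) = (1 − Φ₀) ω₀`` anchored at the sediment-water interface,
which gives the closed form

    age(z) = [z − (Φ₀/c₀)(1 − e^(−c₀ z))] / [(1 − Φ₀) ω₀]

with ω₀ the SWI burial rate of the relevant epoch.  Columns are layered by
age into Holocene (≤ 11,700 yr, bioturbated over the top 10 cm), Pleistocene
(≤ 2.59 Myr) and pre-Quaternary sediment; the Holocene and Pleistocene each
carry their own sedimentation rate and organic-carbon boundary condition,
with age continuous across the epoch boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.optimize import brentq

from .grid_model import GridCell
from .zonation import Zone, assign_zone

__all__ = [
    "Epoch",
    "ColumnMesh",
    "MeshConfig",
    "porosity_at",
    "burial_age",
    "age_at_depth",
    "depth_of_age",
    "isochron_depth",
    "build_mesh",
    "HOLOCENE_MAX_AGE",
    "QUATERNARY_MAX_AGE",
    "BIOTURBATION_DEPTH",
    "SECONDS_PER_YEAR",
]

HOLOCENE_MAX_AGE = 11_700.0  # yr
QUATERNARY_MAX_AGE = 2.59e6  # yr
BIOTURBATION_DEPTH = 0.1  # m; mixed-layer thickness
SECONDS_PER_YEAR = 3.1536e7  # 365-day year


class Epoch(str, Enum):
    HOLOCENE_BIOTURBATED = "holocene_bioturbated"
    HOLOCENE = "holocene"
    PLEISTOCENE = "pleistocene"
    PRE_QUATERNARY = "pre_quaternary"


def porosity_at(z, phi0: float, c0: float):
    """Porosity at depth ``z`` (m) under steady-state compaction."""
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("depth must be non-negative")
    if not 0 < phi0 < 1:
        raise ValueError("phi0 must lie in (0, 1)")
    if not c0 > 0:
        raise ValueError("c0 must be positive")
    out = phi0 * np.exp(-c0 * z)
    return float(out) if out.ndim == 0 else out


def _solid_column(z, phi0: float, c0: float):
    """Cumulative solid (pore-free) thickness above depth z, in m.

    ∫₀ᶻ (1 − Φ(z')) dz' = z − (Φ₀/c₀)(1 − e^(−c₀ z)); the expm1 form keeps
    precision at small c₀ z.
    """
    z = np.asarray(z, dtype=float)
    return z + (phi0 / c0) * np.expm1(-c0 * z)


def burial_age(z, phi0: float, c0: float, omega0: float):
    """Single-epoch burial age (yr) at depth ``z`` (m).

    ``omega0`` is the sedimentation rate at the SWI in cm yr⁻¹.  ``phi0 = 0``
    reduces to the uncompacted ``z / ω₀``.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("depth must be non-negative")
    if phi0 >= 1:
        raise ValueError("phi0 must be < 1")
    if not omega0 > 0:
        raise ValueError("omega0 must be positive")
    omega_m = omega0 / 100.0  # cm/yr -> m/yr
    if phi0 == 0:
        age = z / omega_m
    else:
        if c0 <= 0:
            raise ValueError("c0 must be positive")
        age = _solid_column(z, phi0, c0) / ((1.0 - phi0) * omega_m)
    return float(age) if np.ndim(age) == 0 else age


def _holocene_base_depth(cell: GridCell) -> float:
    """Depth (m) of the 11,700-yr isochron for a cell (unclipped)."""
    target_solid = (
        (1.0 - cell.phi0) * (cell.sed_rate_holocene / 100.0) * HOLOCENE_MAX_AGE
    )
    return _invert_solid(target_solid, cell.phi0, cell.c0)


def _invert_solid(target: float, phi0: float, c0: float) -> float:
    """Invert the cumulative-solid function by bracketed root finding."""
    if target <= 0:
        return 0.0
    # solid(z) >= z - phi0/c0, so z = target + phi0/c0 always brackets above
    hi = target + phi0 / c0 + 1.0
    return brentq(
        lambda z: _solid_column(z, phi0, c0) - target, 0.0, hi, xtol=1e-12, rtol=1e-14
    )


def age_at_depth(cell: GridCell, z) -> np.ndarray | float:
    """Two-epoch burial age (yr) at depth ``z`` (m) for a grid cell.

    The Holocene rate applies above the 11,700-yr isochron; the Pleistocene
    rate below it.  Age is continuous across the boundary.  Ages keep
    accumulating below the Quaternary base (callers use the epoch labels to
    restrict the organic-carbon model to Quaternary sediment).
    """
    z = np.asarray(z, dtype=float)
    z_holo = _holocene_base_depth(cell)
    omega_h = (1.0 - cell.phi0) * (cell.sed_rate_holocene / 100.0)
    omega_p = (1.0 - cell.phi0) * (cell.sed_rate_pleistocene / 100.0)
    solid = _solid_column(z, cell.phi0, cell.c0)
    solid_holo = _solid_column(z_holo, cell.phi0, cell.c0)
    age = np.where(
        z <= z_holo,
        solid / omega_h,
        HOLOCENE_MAX_AGE + (solid - solid_holo) / omega_p,
    )
    return float(age) if age.ndim == 0 else age


def isochron_depth(cell: GridCell, target_age: float) -> float:
    """Depth (m) of the ``target_age`` isochron under the raw two-epoch age
    model, with no Quaternary-base or Pleistocene-gap clamping."""
    if target_age < 0:
        raise ValueError("target_age must be non-negative")
    if target_age == 0:
        return 0.0
    if target_age <= HOLOCENE_MAX_AGE:
        target_solid = (
            (1.0 - cell.phi0) * (cell.sed_rate_holocene / 100.0) * target_age
        )
    else:
        z_holo = _holocene_base_depth(cell)
        target_solid = _solid_column(z_holo, cell.phi0, cell.c0) + (1.0 - cell.phi0) * (
            cell.sed_rate_pleistocene / 100.0
        ) * (target_age - HOLOCENE_MAX_AGE)
    return _invert_solid(target_solid, cell.phi0, cell.c0)


def depth_of_age(target_age: float, cell: GridCell) -> float:
    """Depth (m) of the ``target_age`` (yr) isochron; NaN if absent.

    Returns NaN when the cell has no sediment of that age: either the age
    exceeds the age at the Quaternary base, or the cell lacks Pleistocene
    sediment (shelf exposed or glaciated during Pleistocene lowstands) and
    the age is older than the Holocene.
    """
    if target_age == 0:
        return 0.0
    if not cell.has_pleistocene and target_age > HOLOCENE_MAX_AGE:
        return float("nan")
    z = isochron_depth(cell, target_age)
    z_base = min(cell.quaternary_thickness, cell.sediment_thickness)
    if z > z_base:
        return float("nan")
    return z


@dataclass
class MeshConfig:
    """Discretization settings for a sediment column."""

    n_nodes: int = 80  # log-spaced nodes between z_min and the column base
    z_min: float = 0.001  # m; first log-spaced node
    max_depth: float = 10_000.0  # m; cap on resolved depth
    dedupe_tol: float = 1e-9  # m; nodes closer than this are merged

    def validate(self) -> None:
        if self.n_nodes < 4:
            raise ValueError("n_nodes must be at least 4")
        if not 0 < self.z_min < self.max_depth:
            raise ValueError("need 0 < z_min < max_depth")


@dataclass
class ColumnMesh:
    """Discretized vertical column for one cell.

    Node arrays are aligned; ``slab_thickness`` is the midpoint-based slab
    each node represents.  Integrals over the column are taken over the
    intervals between consecutive nodes; epoch and zone boundaries are exact
    mesh nodes, so no interval straddles a boundary.
    """

    depths: np.ndarray  # m, strictly increasing from 0
    porosity: np.ndarray
    age: np.ndarray  # yr
    epoch: np.ndarray  # Epoch values, object dtype
    zone: np.ndarray  # Zone values, object dtype
    slab_thickness: np.ndarray  # m
    z_holocene_base: float
    z_quaternary_base: float

    def __len__(self) -> int:
        return len(self.depths)

    @property
    def n_intervals(self) -> int:
        return max(len(self.depths) - 1, 0)

    def interval_widths(self) -> np.ndarray:
        return np.diff(self.depths)

    def interval_zones(self) -> np.ndarray:
        """Zone of each inter-node interval (taken from its top node)."""
        return self.zone[:-1]

    def interval_epochs(self) -> np.ndarray:
        return self.epoch[:-1]


def _epoch_labels(depths: np.ndarray, ages: np.ndarray, cell: GridCell) -> np.ndarray:
    labels = np.empty(len(depths), dtype=object)
    z_base = min(cell.quaternary_thickness, cell.sediment_thickness)
    # tolerances absorb root-finder residue at inserted isochron nodes
    for i, (z, age) in enumerate(zip(depths, ages)):
        if age > QUATERNARY_MAX_AGE * (1 + 1e-9) or z > z_base + 1e-9:
            labels[i] = Epoch.PRE_QUATERNARY
        elif age > HOLOCENE_MAX_AGE * (1 + 1e-9):
            if cell.has_pleistocene:
                labels[i] = Epoch.PLEISTOCENE
            else:
                labels[i] = Epoch.PRE_QUATERNARY
        elif z <= BIOTURBATION_DEPTH + 1e-12:
            labels[i] = Epoch.HOLOCENE_BIOTURBATED
        else:
            labels[i] = Epoch.HOLOCENE
    return labels


def build_mesh(cell: GridCell, config: MeshConfig | None = None) -> ColumnMesh:
    """Build the discretized column for a cell.

    Log-spaced nodes from ``z_min`` down to the column base (sediment
    thickness capped at ``max_depth``), augmented with exact nodes at the
    SWI, the bioturbation base (0.1 m), the Holocene and Quaternary age
    boundaries, and the redox boundaries (OPD, SMT).
    """
    config = config or MeshConfig()
    config.validate()
    z_max = min(cell.sediment_thickness, config.max_depth)
    if z_max <= 0:
        import warnings

        warnings.warn(f"{cell.cell_id}: zero sediment thickness, empty mesh")
        empty = np.array([])
        return ColumnMesh(
            depths=empty,
            porosity=empty,
            age=empty,
            epoch=np.array([], dtype=object),
            zone=np.array([], dtype=object),
            slab_thickness=empty,
            z_holocene_base=0.0,
            z_quaternary_base=0.0,
        )
    nodes = [0.0]
    if z_max > config.z_min:
        nodes.extend(np.geomspace(config.z_min, z_max, config.n_nodes))
    else:
        nodes.append(z_max)
    z_holo = _holocene_base_depth(cell)
    if cell.has_pleistocene:
        z_quat = min(
            cell.quaternary_thickness,
            cell.sediment_thickness,
            isochron_depth(cell, QUATERNARY_MAX_AGE),
        )
    else:
        z_quat = min(z_holo, cell.quaternary_thickness, cell.sediment_thickness)
    extras = [BIOTURBATION_DEPTH, z_holo, z_quat, cell.opd, cell.smt_depth]
    for z in extras:
        if np.isfinite(z) and 0.0 < z < z_max:
            nodes.append(float(z))
    depths = np.array(sorted(nodes))
    keep = np.ones(len(depths), dtype=bool)
    keep[1:] = np.diff(depths) > config.dedupe_tol
    depths = depths[keep]

    ages = np.asarray(age_at_depth(cell, depths))
    porosity = porosity_at(depths, cell.phi0, cell.c0)
    epoch = _epoch_labels(depths, ages, cell)
    zone = np.array(
        [assign_zone(z, cell.opd, cell.smt_depth) for z in depths], dtype=object
    )
    mids = np.concatenate(
        [[depths[0]], 0.5 * (depths[1:] + depths[:-1]), [depths[-1]]]
    )
    slab = np.diff(mids)
    return ColumnMesh(
        depths=depths,
        porosity=porosity,
        age=ages,
        epoch=epoch,
        zone=zone,
        slab_thickness=slab,
        z_holocene_base=z_holo,
        z_quaternary_base=z_quat,
    )
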