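"""Catabolic zonation of sediment columns.

The reaction network distinguishes three catabolic zones by the dominant
terminal electron acceptor: sediment above the maximum oxygen penetration
depth (OPD) is oxic, sediment between the OPD and the sulfate-methane
transition (SMT) is sulfate-reducing, and sediment beneath the SMT is
methanogenic.  Boundaries are imposed per cell from the redox forcing
fields; the model does not solve for them.

Ties are resolved lower-inclusive: a depth exactly at the OPD belongs to the
sulfate-reducing zone, exactly at the SMT to the methanogenic zone.
"""

from __future__ import annotations

import logging
import math
from enum import Enum
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .grid_model import GridCell
    from .sediment_column import ColumnMesh

__all__ = ["Zone", "assign_zone", "zone_volumes", "effective_smt"]

logger = logging.getLogger(__name__)


class Zone(str, Enum):
    OXIC = "oxic"
    SULFATE = "sulfate"
    METHANOGENIC = "methanogenic"


def effective_smt(smt_depth: float, sediment_thickness: float) -> float:
    """SMT depth to use for zonation; columns with no reported SMT (NaN)
    are treated as sulfate-reducing to the basement."""
    if not math.isfinite(smt_depth):
        logger.info("missing SMT treated as basement depth %.3f m", sediment_thickness)
        return sediment_thickness
    return smt_depth


def assign_zone(z: float, opd: float, smt: float) -> Zone:
    """Catabolic zone at depth ``z`` (m) given the redox boundaries.

    Intervals are half-open, lower-inclusive: ``[0, opd)`` oxic,
    ``[opd, smt)`` sulfate-reducing, ``[smt, ∞)`` methanogenic.
    """
    if not 0 <= opd:
        raise ValueError("opd must be non-negative")
    if math.isfinite(smt) and opd > smt:
        raise ValueError(f"opd ({opd}) must not exceed smt ({smt})")
    if z < opd:
        return Zone.OXIC
    if not math.isfinite(smt) or z < smt:
        return Zone.SULFATE
    return Zone.METHANOGENIC


def zone_volumes(cell: "GridCell", mesh: "ColumnMesh") -> dict:
    """Bulk and solid sediment volume per catabolic zone, km³.

    Volumes are integrated over the inter-node intervals of the mesh; the
    redox boundaries are exact mesh nodes, so each interval lies wholly in
    one zone and the three volumes partition the column exactly.

    Returns a dict with ``bulk`` and ``solid`` sub-dicts keyed by Zone.
    """
    area = cell.area  # km²
    bulk = {z: 0.0 for z in Zone}
    solid = {z: 0.0 for z in Zone}
    if len(mesh) < 2:
        return {"bulk": bulk, "solid": solid}
    widths = mesh.interval_widths() / 1000.0  # m -> km
    zones = mesh.interval_zones()
    # trapezoid of (1 - porosity) over each interval for the solid variant
    one_minus_phi = 1.0 - mesh.porosity
    mean_solid = 0.5 * (one_minus_phi[1:] + one_minus_phi[:-1])
    for w, zn, ms in zip(widths, zones, mean_solid):
        bulk[zn] += area * w
        solid[zn] += area * w * ms
    return {"bulk": bulk, "solid": solid}
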