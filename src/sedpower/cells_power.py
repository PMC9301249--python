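"""Cell-abundance profiles and per-cell catabolic power.

Subseafloor cell abundance follows the power law ``Y(z) = b z^m`` (cells per
bulk cm³, z in mbsf), held constant over the bioturbated top 10 cm at
``Y_zbio = b · 0.1^m``.  Per-cell power is the rate of Gibbs-energy release
divided by the cells that share it,

    P = r · |ΔG_r| / Y      (W cell⁻¹)

with ``r`` the volumetric organic-carbon degradation rate in g C per bulk
cm³ per second and ΔG_r in J per g C.  The dry-volume RCM rate R_POC is
converted to the bulk-volume basis by the solid fraction (1 − Φ) and from
years to seconds.  All cells at a node are assumed to perform the catabolic
metabolism of the node's zone; powers are reported positive for exergonic
reactions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sediment_column import BIOTURBATION_DEPTH, SECONDS_PER_YEAR

__all__ = [
    "CellPowerProfile",
    "cell_density",
    "cells_in_slab",
    "power_per_cell",
    "bulk_rate",
]


@dataclass
class CellPowerProfile:
    """Per-node abundance and power state of one column."""

    cell_density: np.ndarray  # cells per bulk cm^3
    power_per_cell: np.ndarray  # W per cell; NaN where out of model
    volumetric_power: np.ndarray  # W per bulk cm^3


def cell_density(z, b: float, m_exp: float):
    """Cell abundance (cells cm⁻³ bulk) at depth ``z`` (mbsf, > 0).

    Depths within the bioturbated layer (z ≤ 0.1 m) return the constant
    mixed-layer abundance ``b · 0.1^m``.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z <= 0):
        raise ValueError("depth must be positive")
    if not b > 0:
        raise ValueError("b must be positive")
    out = b * np.maximum(z, BIOTURBATION_DEPTH) ** m_exp
    return float(out) if out.ndim == 0 else out


def cells_in_slab(z1: float, z2: float, b: float, m_exp: float, area: float) -> float:
    """Total cells between depths ``z1`` and ``z2`` (m) under ``area`` cm².

    Closed-form integral of the abundance power law over depth; the factor
    100 converts the metre depth integral to the cm³ basis of the density.
    The portion of the slab inside the bioturbated layer uses the constant
    mixed-layer abundance.
    """
    if not 0 < z1 <= z2:
        raise ValueError("need 0 < z1 <= z2")
    if z2 == z1:
        return 0.0

    def _power_integral(lo: float, hi: float) -> float:
        # ∫ b z^m dz on [lo, hi], lo >= zbio
        if m_exp == -1.0:
            return b * np.log(hi / lo)
        p = m_exp + 1.0
        return b * (hi**p - lo**p) / p

    zb = BIOTURBATION_DEPTH
    total = 0.0
    if z1 < zb:
        hi = min(z2, zb)
        total += b * zb**m_exp * (hi - z1)
    if z2 > zb:
        lo = max(z1, zb)
        total += _power_integral(lo, z2)
    return area * 100.0 * total


def bulk_rate(rpoc_dry, porosity):
    """Convert dry-basis R_POC (g C cm⁻³ yr⁻¹) to bulk g C cm⁻³ s⁻¹."""
    return np.asarray(rpoc_dry) * (1.0 - np.asarray(porosity)) / SECONDS_PER_YEAR


def power_per_cell(r, dg_per_gc, y):
    """Per-cell power P = r·|ΔG_r|/Y, W cell⁻¹.

    ``r`` in g C per bulk cm³ per second, ``dg_per_gc`` in J per g C (sign
    ignored; exergonic reactions are reported as positive power), ``y`` in
    cells per bulk cm³.
    """
    r = np.asarray(r, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(r < 0):
        raise ValueError("rate must be non-negative")
    if np.any(y <= 0):
        raise ValueError("cell abundance must be positive")
    out = r * np.abs(dg_per_gc) / y
    return float(out) if out.ndim == 0 else out
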