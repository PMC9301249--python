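"""Seeded synthetic global grids with the statistical structure of real
seafloor forcings.

The generator stands in for the global compilations the analysis needs
(water depth, sedimentation rate, seafloor POC, oxygen penetration, SMT
depth, cell-abundance parameters).  It does not reproduce real geography;
it reproduces the orderings and magnitudes that drive the analysis:

* shallow shelves: fast sedimentation, high POC, mm-cm oxygen penetration,
  m-scale SMT, high cell abundance with steep decline;
* abyssal plains: slow sedimentation, low POC, metres to tens of metres of
  oxygen penetration, SMT hundreds of metres deep, sparse cells;
* a configurable fraction of shelf cells lacking Pleistocene sediment
  (exposed or glaciated during Pleistocene sea-level lowstands).

All randomness flows from one seed through a counter-based per-cell
substream, so any single cell is reproducible in isolation and the grid is
independent of traversal order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .grid_model import (
    Domain,
    GlobalGrid,
    GridCell,
    cell_id_for,
    classify_domain,
)
from .sediment_column import HOLOCENE_MAX_AGE, QUATERNARY_MAX_AGE, age_at_depth

__all__ = [
    "WorldConfig",
    "SedRateCurve",
    "generate_world",
    "sedimentation_rate",
    "bioturbation_coefficient",
    "a_from_sedrate",
    "redox_depth_fields",
]


@dataclass
class SedRateCurve:
    """Double-sigmoid water-depth → sedimentation-rate curve (cm yr⁻¹).

    ω(z) = ω₁/(1+(z/z₁)^c₁) + ω₂/(1+(z/z₂)^c₂): a fast shelf component
    rolling off across the shelf break plus a slow pelagic component rolling
    off across the abyssal transition.
    """

    omega1: float = 0.08  # cm/yr, shelf component amplitude
    z1: float = 200.0  # m, shelf roll-off depth
    c1: float = 2.0
    omega2: float = 0.002  # cm/yr, pelagic component amplitude
    z2: float = 4000.0  # m, abyssal roll-off depth
    c2: float = 3.0

    def validate(self) -> None:
        for name in ("omega1", "z1", "c1", "omega2", "z2", "c2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"sed-rate curve parameter {name} must be > 0")


@dataclass
class OpdParams:
    """Oxygen-penetration-depth scaling: deeper water and less organic
    loading let oxygen reach further into the sediment."""

    coeff: float = 0.003  # m at the 100 m / 0.01 g C cm^-3 reference
    depth_exp: float = 2.0
    poc_ref: float = 0.01  # g C cm^-3
    poc_exp: float = 1.0
    clip: tuple[float, float] = (5e-4, 80.0)
    noise_gsd: float = 1.2
    noise_clip: float = 1.6  # hard bound on the lognormal multiplier


@dataclass
class SmtParams:
    """Sulfate-methane-transition scaling: high POC flux pulls the SMT up."""

    coeff: float = 11.0  # m at the reference point
    depth_exp: float = 0.7
    poc_ref: float = 0.01
    poc_exp: float = 0.5
    clip: tuple[float, float] = (1.2, 2000.0)
    noise_gsd: float = 1.2
    noise_clip: float = 1.6


@dataclass
class DomainParams:
    """Per-domain generator settings."""

    depth_range: tuple[float, float]  # m, uniform water-depth draw
    thickness_range: tuple[float, float]  # m, log-uniform sediment thickness
    poc0_median: float  # g C cm^-3 dry
    poc0_gsd: float  # geometric standard deviation
    phi0: float
    c0: float  # m^-1
    log10_b_range: tuple[float, float]  # cells cm^-3 at 1 mbsf
    m_range: tuple[float, float]  # power-law exponent (negative)


def _default_domains() -> dict[Domain, DomainParams]:
    return {
        Domain.SHELF: DomainParams(
            depth_range=(10.0, 200.0),
            thickness_range=(1200.0, 8000.0),
            poc0_median=0.035,
            poc0_gsd=1.5,
            phi0=0.60,
            c0=1.5e-3,
            log10_b_range=(8.2, 9.2),
            m_range=(-0.85, -0.60),
        ),
        Domain.MARGIN: DomainParams(
            depth_range=(200.0, 3500.0),
            thickness_range=(200.0, 4000.0),
            poc0_median=0.018,
            poc0_gsd=1.5,
            phi0=0.74,
            c0=1.0e-3,
            log10_b_range=(6.0, 7.2),
            m_range=(-0.80, -0.55),
        ),
        Domain.ABYSS: DomainParams(
            depth_range=(3500.0, 6000.0),
            thickness_range=(150.0, 1200.0),
            poc0_median=0.005,
            poc0_gsd=1.5,
            phi0=0.85,
            c0=5.0e-4,
            log10_b_range=(4.0, 5.5),
            m_range=(-0.70, -0.45),
        ),
    }


@dataclass
class WorldConfig:
    """Full configuration of a synthetic global grid."""

    n_lat: int = 20
    n_lon: int = 40
    seed: int = 0
    #: target areal fractions (world-ocean values); abyss takes the rest
    fraction_shelf: float = 0.063
    fraction_margin: float = 0.108
    sedrate_curve: SedRateCurve = field(default_factory=SedRateCurve)
    sedrate_gsd: float = 1.3  # per-cell lognormal scatter on ω
    sedrate_noise_clip: float = 2.0
    pleistocene_omega_factor: float = 0.9  # ω_pleist / ω_holo
    pleistocene_poc_factor: float = 1.0  # POC0_pleist / POC0_holo
    a_coeff: float = 1.0  # yr (cm/yr)^a_exponent
    a_exponent: float = 1.6
    nu: float = 0.125
    db_surface: float = 30.0  # cm^2/yr extrapolated to zero water depth
    db_efold: float = 1500.0  # m, water-depth e-folding of mixing intensity
    db_clip: tuple[float, float] = (0.59, 27.0)
    opd_params: OpdParams = field(default_factory=OpdParams)
    smt_params: SmtParams = field(default_factory=SmtParams)
    pleistocene_gap_fraction: float = 0.3  # shelf cells missing Pleistocene
    domains: dict[Domain, DomainParams] = field(default_factory=_default_domains)
    poc_noise_clip: float = 2.5

    def validate(self) -> None:
        if self.n_lat < 1 or self.n_lon < 1:
            raise ValueError("grid dimensions must be positive")
        if abs(180.0 / self.n_lat - 360.0 / self.n_lon) > 1e-9:
            raise ValueError("grid cells must be square: 180/n_lat == 360/n_lon")
        f = (self.fraction_shelf, self.fraction_margin)
        if any(x < 0 or x > 1 for x in f) or sum(f) > 1:
            raise ValueError("domain fractions must lie in [0,1] and sum <= 1")
        if not 0 <= self.pleistocene_gap_fraction <= 1:
            raise ValueError("pleistocene_gap_fraction must lie in [0, 1]")
        self.sedrate_curve.validate()
        for name in ("a_coeff", "a_exponent", "db_surface", "db_efold"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not self.db_clip[0] <= self.db_clip[1]:
            raise ValueError("db_clip must be ordered")

    @property
    def resolution(self) -> float:
        return 180.0 / self.n_lat


def sedimentation_rate(water_depth: float, curve: SedRateCurve) -> float:
    """Holocene sedimentation rate (cm yr⁻¹) at a water depth (m)."""
    if not water_depth > 0:
        raise ValueError("water_depth must be positive")
    curve.validate()
    z = water_depth
    return curve.omega1 / (1.0 + (z / curve.z1) ** curve.c1) + curve.omega2 / (
        1.0 + (z / curve.z2) ** curve.c2
    )


def bioturbation_coefficient(
    water_depth: float,
    db_surface: float = 30.0,
    db_efold: float = 1500.0,
    db_clip: tuple[float, float] = (0.59, 27.0),
) -> float:
    """Bioturbation coefficient (cm² yr⁻¹), non-increasing in water depth.

    An exponential decline with water depth, clipped into the observed
    global range.
    """
    if not water_depth > 0:
        raise ValueError("water_depth must be positive")
    raw = db_surface * math.exp(-water_depth / db_efold)
    return float(min(max(raw, db_clip[0]), db_clip[1]))


def a_from_sedrate(omega: float, coeff: float = 1.0, exponent: float = 1.6) -> float:
    """RCM ``a`` parameter (yr) from the sedimentation rate (cm yr⁻¹).

    Power law ``a = coeff · ω^(−exponent)``: slow burial means long
    source-to-deposition transit and more degraded, less reactive organic
    matter (large a); rapid burial delivers fresh material (small a).
    """
    if not omega > 0:
        raise ValueError("omega must be positive")
    return coeff * omega ** (-exponent)


def redox_depth_fields(
    cell_like: dict,
    opd_params: OpdParams,
    smt_params: SmtParams,
    noise_opd: float = 1.0,
    noise_smt: float = 1.0,
) -> tuple[float, float]:
    """Oxygen penetration depth and SMT depth (m) for a cell.

    ``cell_like`` needs ``water_depth`` (m) and ``poc0`` (g C cm⁻³).  OPD
    grows with water depth and shrinks with organic loading; the SMT
    shallows where POC is high.  The pair is clamped so opd ≤ smt.
    """
    zw = cell_like["water_depth"]
    poc0 = cell_like["poc0"]
    if not zw > 0 or not poc0 > 0:
        raise ValueError("water_depth and poc0 must be positive")
    op, sp = opd_params, smt_params
    opd = (
        op.coeff
        * (zw / 100.0) ** op.depth_exp
        * (op.poc_ref / poc0) ** op.poc_exp
        * noise_opd
    )
    opd = min(max(opd, op.clip[0]), op.clip[1])
    smt = (
        sp.coeff
        * (zw / 100.0) ** sp.depth_exp
        * (sp.poc_ref / poc0) ** sp.poc_exp
        * noise_smt
    )
    smt = min(max(smt, sp.clip[0]), sp.clip[1])
    if opd > smt:
        opd = smt
    return opd, smt


def _clipped_lognormal(rng: np.random.Generator, gsd: float, clip: float) -> float:
    """Multiplicative lognormal noise with a hard bound on the factor."""
    mult = math.exp(rng.normal(0.0, math.log(gsd)))
    return min(max(mult, 1.0 / clip), clip)


def _cell_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def generate_world(config: WorldConfig | None = None) -> GlobalGrid:
    """Generate a deterministic synthetic global grid from a config."""
    config = config or WorldConfig()
    config.validate()
    res = config.resolution
    lats = -90.0 + res * (np.arange(config.n_lat) + 0.5)
    lons = -180.0 + res * (np.arange(config.n_lon) + 0.5)
    cells: list[GridCell] = []
    f_shelf, f_margin = config.fraction_shelf, config.fraction_margin
    for idx in range(config.n_lat * config.n_lon):
        i, j = divmod(idx, config.n_lon)
        lat, lon = float(lats[i]), float(lons[j])
        rng = _cell_rng(config.seed, idx)
        u = rng.uniform()
        if u < f_shelf:
            target = Domain.SHELF
        elif u < f_shelf + f_margin:
            target = Domain.MARGIN
        else:
            target = Domain.ABYSS
        dp_target = config.domains[target]
        water_depth = rng.uniform(*dp_target.depth_range)
        domain = classify_domain(water_depth, lat)
        dp = config.domains[domain]

        log_lo, log_hi = np.log(dp.thickness_range)
        thickness = float(np.exp(rng.uniform(log_lo, log_hi)))

        omega_h = sedimentation_rate(water_depth, config.sedrate_curve)
        omega_h *= _clipped_lognormal(rng, config.sedrate_gsd, config.sedrate_noise_clip)
        omega_p = omega_h * config.pleistocene_omega_factor

        poc0_h = dp.poc0_median * _clipped_lognormal(
            rng, dp.poc0_gsd, config.poc_noise_clip
        )
        poc0_p = poc0_h * config.pleistocene_poc_factor

        a_h = a_from_sedrate(omega_h, config.a_coeff, config.a_exponent)
        a_p = a_from_sedrate(omega_p, config.a_coeff, config.a_exponent)

        db = bioturbation_coefficient(
            water_depth, config.db_surface, config.db_efold, config.db_clip
        )

        noise_opd = _clipped_lognormal(
            rng, config.opd_params.noise_gsd, config.opd_params.noise_clip
        )
        noise_smt = _clipped_lognormal(
            rng, config.smt_params.noise_gsd, config.smt_params.noise_clip
        )
        opd, smt = redox_depth_fields(
            {"water_depth": water_depth, "poc0": poc0_h},
            config.opd_params,
            config.smt_params,
            noise_opd,
            noise_smt,
        )

        log10_b = rng.uniform(*dp.log10_b_range)
        m_cells = rng.uniform(*dp.m_range)

        has_pleist = True
        if domain is Domain.SHELF:
            has_pleist = rng.uniform() >= config.pleistocene_gap_fraction

        cell = GridCell(
            cell_id=cell_id_for(lat, lon),
            lon_center=lon,
            lat_center=lat,
            resolution=res,
            water_depth=water_depth,
            sediment_thickness=thickness,
            quaternary_thickness=thickness,  # provisional; refined below
            domain=domain,
            sed_rate_holocene=omega_h,
            sed_rate_pleistocene=omega_p,
            poc0_holocene=poc0_h,
            poc0_pleistocene=poc0_p,
            a_holocene=a_h,
            a_pleistocene=a_p,
            nu=config.nu,
            phi0=dp.phi0,
            c0=dp.c0,
            db=db,
            opd=opd,
            smt_depth=smt,
            b_cells=10.0**log10_b,
            m_cells=m_cells,
            has_pleistocene=has_pleist,
        )
        cell.quaternary_thickness = _quaternary_thickness(cell)
        cells.append(cell)
    return GlobalGrid(
        cells=cells,
        resolution=res,
        seed=config.seed,
        provenance=f"sedpower synthetic world, seed={config.seed}, "
        f"{config.n_lat}x{config.n_lon}",
    )


def _quaternary_thickness(cell: GridCell) -> float:
    """Depth of the base of the modeled (Quaternary) section, m.

    The depth of the 2.59-Myr isochron under the cell's two-epoch age model,
    capped by the sediment thickness; cells lacking Pleistocene sediment
    carry a Quaternary section only down to the 11,700-yr isochron.
    """
    from .sediment_column import isochron_depth

    limit_age = HOLOCENE_MAX_AGE if not cell.has_pleistocene else QUATERNARY_MAX_AGE
    if age_at_depth(cell, cell.sediment_thickness) <= limit_age:
        return cell.sediment_thickness
    return float(isochron_depth(cell, limit_age))
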