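"""Gibbs energies of the three zone-specific catabolic reactions.

Acetate (CH₃COO⁻) serves as the proxy organic substrate.  The three
catabolisms, one per zone, are

    aerobic heterotrophy:   CH₃COO⁻ + 2 O₂(aq)  → 2 HCO₃⁻ + H⁺
    sulfate reduction:      CH₃COO⁻ + SO₄²⁻     → 2 HCO₃⁻ + HS⁻
    methanogenesis:         CH₃COO⁻ + H₂O       → CH₄(aq) + HCO₃⁻

Energy yields follow ΔG_r = ΔG⁰_r + R·T·ln Q_r with Q_r = Π a_i^ν_i and
activities a_i = m_i·γ_i from molalities and extended Debye-Hückel activity
coefficients, log₁₀ γ = −A z² √I / (1 + åB √I) + b_γ I.  Standard-state
Gibbs energies at the reference 5 °C / 100 bar are configuration constants
from standard thermodynamic compilations; one representative pore-water
chemistry per zone is applied globally (oxic values South-Pacific-Gyre-like,
anoxic values Limfjorden/Peru-Margin-like).  Water activity is unity and H⁺
activity is supplied as 10^(−pH).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .zonation import Zone

__all__ = [
    "Reaction",
    "GeochemContext",
    "ionic_strength",
    "activity_coefficient",
    "reaction_quotient",
    "gibbs_energy",
    "energy_per_g_c",
    "default_reactions",
    "default_contexts",
    "zone_energies",
    "GAS_CONSTANT",
    "G_C_PER_MOL_ACETATE",
]

GAS_CONSTANT = 8.314  # J mol^-1 K^-1
G_C_PER_MOL_ACETATE = 24.022  # g C per mole of acetate turned over

#: element compositions used for the programmatic balance check
_COMPOSITION: dict[str, dict[str, float]] = {
    "CH3COO-": {"C": 2, "H": 3, "O": 2, "charge": -1},
    "O2(aq)": {"O": 2, "charge": 0},
    "HCO3-": {"C": 1, "H": 1, "O": 3, "charge": -1},
    "H+": {"H": 1, "charge": 1},
    "SO4-2": {"S": 1, "O": 4, "charge": -2},
    "HS-": {"S": 1, "H": 1, "charge": -1},
    "CH4(aq)": {"C": 1, "H": 4, "charge": 0},
    "H2O": {"H": 2, "O": 1, "charge": 0},
}


@dataclass(frozen=True)
class Reaction:
    """Catabolic reaction: stoichiometry (products positive) plus ΔG⁰_r."""

    name: str
    stoichiometry: dict[str, float]
    dg0: float  # J mol^-1 at reference T, P
    g_c_per_mol: float = G_C_PER_MOL_ACETATE

    def check_balance(self, tol: float = 1e-9) -> None:
        """Raise if any element or the charge fails to balance."""
        totals: dict[str, float] = {}
        for species, coeff in self.stoichiometry.items():
            comp = _COMPOSITION.get(species)
            if comp is None:
                raise ValueError(f"{self.name}: unknown species {species!r}")
            for element, count in comp.items():
                totals[element] = totals.get(element, 0.0) + coeff * count
        bad = {el: v for el, v in totals.items() if abs(v) > tol}
        if bad:
            raise ValueError(f"{self.name}: unbalanced {bad}")


@dataclass
class DebyeHuckelParams:
    """Extended Debye-Hückel constants (cold seawater defaults)."""

    A: float = 0.5092  # kg^0.5 mol^-0.5
    aB: float = 1.2  # å·B product, kg^0.5 mol^-0.5 basis
    b_gamma: float = 0.041  # kg mol^-1, charged species
    b_gamma_neutral: float = 0.0  # neutral species: γ = 1 by default


@dataclass
class GeochemContext:
    """Representative pore-water chemistry for one catabolic zone."""

    molalities: dict[str, float]  # mol per kg H2O
    charges: dict[str, int]
    pH: float = 7.8
    temperature: float = 278.15  # K (5 °C)
    pressure: float = 100.0  # bar
    dh: DebyeHuckelParams = field(default_factory=DebyeHuckelParams)

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")
        for sp, m in self.molalities.items():
            if m < 0:
                raise ValueError(f"negative molality for {sp}")

    def ionic_strength(self) -> float:
        return ionic_strength(self.molalities, self.charges)

    def activity(self, species: str) -> float:
        """Activity of a species: m·γ, with H⁺ from pH and water unity."""
        if species == "H2O":
            return 1.0
        if species == "H+":
            return 10.0 ** (-self.pH)
        if species not in self.molalities:
            raise ValueError(f"species {species!r} missing from context")
        m = self.molalities[species]
        if m <= 0:
            raise ValueError(f"species {species!r} has zero molality")
        z = self.charges.get(species, 0)
        gamma = activity_coefficient(z, self.ionic_strength(), self.dh)
        return m * gamma


def ionic_strength(molalities: dict[str, float], charges: dict[str, int]) -> float:
    """I = ½ Σ m_i z_i² over all charged species, mol kg⁻¹."""
    total = 0.0
    for species, m in molalities.items():
        if species not in charges:
            raise ValueError(f"species {species!r} has molality but no charge")
        total += m * charges[species] ** 2
    return 0.5 * total


def activity_coefficient(
    charge: int, ionic: float, dh: DebyeHuckelParams | None = None
) -> float:
    """Extended Debye-Hückel individual activity coefficient γ.

    ``log₁₀ γ = −A z² √I / (1 + åB √I) + b_γ I``; γ → 1 as I → 0, and
    neutral species with b_γ = 0 have γ = 1 exactly.
    """
    if ionic < 0:
        raise ValueError("ionic strength must be non-negative")
    dh = dh or DebyeHuckelParams()
    b = dh.b_gamma if charge != 0 else dh.b_gamma_neutral
    sqrt_i = math.sqrt(ionic)
    log10_gamma = -dh.A * charge**2 * sqrt_i / (1.0 + dh.aB * sqrt_i) + b * ionic
    return 10.0**log10_gamma


def reaction_quotient(reaction: Reaction, context: GeochemContext) -> float:
    """Q_r = Π a_i^ν_i with products positive, reactants negative."""
    log_q = 0.0
    for species, coeff in reaction.stoichiometry.items():
        log_q += coeff * math.log(context.activity(species))
    return math.exp(log_q)


def gibbs_energy(reaction: Reaction, context: GeochemContext) -> float:
    """ΔG_r = ΔG⁰_r + R·T·ln Q_r, J per mole of reaction turnover."""
    q = reaction_quotient(reaction, context)
    if not q > 0:
        raise ValueError("reaction quotient must be positive")
    return reaction.dg0 + GAS_CONSTANT * context.temperature * math.log(q)


def energy_per_g_c(dg: float, reaction: Reaction) -> float:
    """Convert J per mole of reaction to J per g of organic C turned over."""
    return dg / reaction.g_c_per_mol


# ------------------------------------------------------------------ defaults


def default_reactions() -> dict[Zone, Reaction]:
    """The three acetate catabolisms with reference-state ΔG⁰_r (5 °C, 100 bar)."""
    rxns = {
        Zone.OXIC: Reaction(
            name="aerobic_heterotrophy",
            stoichiometry={"CH3COO-": -1, "O2(aq)": -2, "HCO3-": 2, "H+": 1},
            dg0=-844_000.0,
        ),
        Zone.SULFATE: Reaction(
            name="sulfate_reduction",
            stoichiometry={"CH3COO-": -1, "SO4-2": -1, "HCO3-": 2, "HS-": 1},
            dg0=-47_600.0,
        ),
        Zone.METHANOGENIC: Reaction(
            name="methanogenesis",
            stoichiometry={"CH3COO-": -1, "H2O": -1, "CH4(aq)": 1, "HCO3-": 1},
            dg0=-31_000.0,
        ),
    }
    for r in rxns.values():
        r.check_balance()
    return rxns


_SEAWATER_IONS = {
    "Na+": 0.4686,
    "Cl-": 0.5459,
    "Mg+2": 0.0528,
    "Ca+2": 0.0103,
    "K+": 0.0102,
}
_SEAWATER_CHARGES = {
    "Na+": 1,
    "Cl-": -1,
    "Mg+2": 2,
    "Ca+2": 2,
    "K+": 1,
    "SO4-2": -2,
    "HCO3-": -1,
    "HS-": -1,
    "CH3COO-": -1,
    "O2(aq)": 0,
    "CH4(aq)": 0,
}


def default_contexts() -> dict[Zone, GeochemContext]:
    """One representative pore-water chemistry per catabolic zone.

    Oxic: oligotrophic abyssal clay pore water (well-oxygenated, low
    substrate).  Sulfate-reducing: organic-rich anoxic margin pore water with
    near-seawater sulfate.  Methanogenic: sulfate-depleted, methane-charged
    pore water.  All at 5 °C and 100 bar.
    """
    oxic = GeochemContext(
        molalities={
            **_SEAWATER_IONS,
            "SO4-2": 0.0282,
            "O2(aq)": 1.5e-4,
            "HCO3-": 2.4e-3,
            "CH3COO-": 1.0e-6,
        },
        charges=_SEAWATER_CHARGES,
        pH=7.8,
    )
    sulfate = GeochemContext(
        molalities={
            **_SEAWATER_IONS,
            "SO4-2": 0.020,
            "HCO3-": 4.0e-3,
            "HS-": 1.0e-6,
            "CH3COO-": 1.0e-6,
        },
        charges=_SEAWATER_CHARGES,
        pH=7.5,
    )
    methanogenic = GeochemContext(
        molalities={
            **_SEAWATER_IONS,
            "HCO3-": 8.0e-3,
            "CH4(aq)": 2.0e-2,
            "CH3COO-": 1.0e-6,
        },
        charges=_SEAWATER_CHARGES,
        pH=7.5,
    )
    return {Zone.OXIC: oxic, Zone.SULFATE: sulfate, Zone.METHANOGENIC: methanogenic}


def zone_energies(
    reactions: dict[Zone, Reaction] | None = None,
    contexts: dict[Zone, GeochemContext] | None = None,
) -> dict[Zone, dict[str, float]]:
    """Per-zone Gibbs energies under the representative chemistries.

    Returns, per zone: ``dg_mol`` (J per mol acetate), ``dg_gc`` (J per g C)
    and ``q`` (reaction quotient).  Raw signed values are retained; power
    calculations take the magnitude of exergonic energies downstream.
    """
    reactions = reactions or default_reactions()
    contexts = contexts or default_contexts()
    out: dict[Zone, dict[str, float]] = {}
    for zone, rxn in reactions.items():
        ctx = contexts[zone]
        q = reaction_quotient(rxn, ctx)
        dg = gibbs_energy(rxn, ctx)
        out[zone] = {"dg_mol": dg, "dg_gc": energy_per_g_c(dg, rxn), "q": q}
    return out
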