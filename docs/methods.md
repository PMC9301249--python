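# Methods

This note documents the models behind `sedpower`, the defaults it ships,
the numerical choices, and what its synthetic worlds do and do not
represent.

## Sediment column and burial age

Porosity follows steady-state (Athy-type) compaction, Φ(z) = Φ₀·e^(−c₀·z),
with surface porosity Φ₀ and compaction length scale c₀ (m⁻¹) set per
depositional domain.  Burial is described by conservation of the
solid-volume flux: (1 − Φ(z))·ω(z) equals its value at the sediment–water
interface (SWI), so the burial age at depth z has the closed form

    age(z) = [z − (Φ₀/c₀)(1 − e^(−c₀ z))] / [(1 − Φ₀) ω₀]

with ω₀ the SWI sedimentation rate of the relevant epoch (cm yr⁻¹,
converted to m yr⁻¹ internally).  Columns are layered by age: Holocene
(≤ 11,700 yr; bioturbated over the top 0.1 m), Pleistocene (≤ 2.59 Myr) and
pre-Quaternary.  Each epoch has its own sedimentation rate and organic
boundary condition; age is continuous across the boundary.  The inverse
(depth of an age isochron) is obtained by bracketed root finding on the
cumulative-solid function (xtol 10⁻¹² m) and returns a missing-value marker
for cells that have no sediment of the requested age, either because the
column bottoms out or because the cell lacks Pleistocene sediment.

The year is 3.1536×10⁷ s (365 d) for all rate conversions.

## Organic carbon: reactive continuum model

Initial reactivity is gamma-distributed over first-order rate constants k
with shape ν and scale 1/a; the defaults use ν = 0.125 everywhere (fresh
organic matter; observed site-to-site variation in ν is small) and tie a to
the sedimentation rate through a power law a = ω^(−1.6) yr (slow burial →
long pre-depositional transit → less reactive input).  Under steady state
each component decays independently along the age coordinate, giving

    POC(t)   = POC₀ (a/(a+t))^ν          (g C per cm³ dry sediment)
    R_POC(t) = ν/(a+t) · POC(t)          (positive degradation rate)

These closed forms are the production path; they are verified against
adaptive-quadrature oracles of the underlying k-integrals to 10⁻⁸ relative
across the full parameter range of the synthetic worlds.  POC is carried on
a dry-volume basis; volumetric (bulk) totals multiply by (1 − Φ).
Degradation is reported as a positive rate; the conservation-equation sign
convention is absorbed there.  Pre-Quaternary sediment is outside the POC
model and carries zero stock and degradation; the 2.59-Myr isochron is an
exact mesh node so the cutoff never falls inside an integration interval.

Within the bioturbated layer the production path evaluates the closed form
at the local burial age, i.e. mixing is not applied to the analytic POC
profile.  The multi-G solver exists to quantify exactly this approximation:
it discretizes the continuum into nk log-spaced pools between the 10⁻⁶ and
1 − 10⁻⁶ gamma quantiles (edge pools absorb the tails, so pool masses
telescope to POC₀ exactly), assigns each pool its mass-weighted mean rate
constant, and solves each pool's steady state with advection, first-order
decay, and bioturbation (constant D_b over the top 0.1 m, zero below; the
mixed layer gets a fine tridiagonal finite-difference solve with a
zero-gradient base condition, and below it the advection–decay balance is
integrated exactly per mesh interval along the age coordinate).  With
D_b = 0 and 200 pools it reproduces the closed form to better than 1%
(binning error only); with D_b > 0 it shows the expected downward transport
of fresh POC.

## Mesh

Columns are discretized on ~80 log-spaced nodes from 10⁻³ m to the column
base (sediment thickness, capped at 10,000 m), augmented with exact nodes
at the SWI, the bioturbation base (0.1 m), the 11,700-yr and 2.59-Myr
isochrons, the OPD and the SMT.  Because every epoch and zone boundary is a
node, interval-based integrals (trapezoid between adjacent nodes, interval
labeled by its upper node) partition the column exactly; zone volumes sum
to the total column volume to 10⁻⁹ relative, and mesh refinement changes
integrated stocks by well under 0.5%.

## Zonation

Sediment above the cell's maximum oxygen penetration depth is oxic, between
OPD and SMT sulfate-reducing, and below the SMT methanogenic.  Boundaries
are forcings, not model outputs: the pipeline deliberately does not solve
dissolved O₂/sulfate/methane transport.  Ties are lower-inclusive (a depth
exactly at the OPD is sulfate-reducing; exactly at the SMT methanogenic).
Cells with no reported SMT are treated as sulfate-reducing to the basement.
Transition-zone metabolisms (anaerobic methane oxidation, nitrification,
anammox), fermentation, and nitrate/Fe/Mn reduction are out of scope.

## Energetics

Acetate is the proxy organic substrate.  The three zone catabolisms are

    aerobic heterotrophy:  CH₃COO⁻ + 2 O₂ → 2 HCO₃⁻ + H⁺      ΔG⁰ = −844 kJ mol⁻¹
    sulfate reduction:     CH₃COO⁻ + SO₄²⁻ → 2 HCO₃⁻ + HS⁻    ΔG⁰ = −47.6 kJ mol⁻¹
    methanogenesis:        CH₃COO⁻ + H₂O → CH₄ + HCO₃⁻        ΔG⁰ = −31 kJ mol⁻¹

ΔG⁰ᵣ at the reference state (5 °C, 100 bar) are configuration constants
from standard thermodynamic compilations; computing them from equations of
state is deliberately out of scope.  In-situ energies use
ΔG = ΔG⁰ + RT·ln Q with activities m·γ, γ from the extended Debye-Hückel
equation log₁₀ γ = −A z² √I/(1 + åB √I) + b_γ I (defaults A = 0.5092,
åB = 1.2, b_γ = 0.041 for ions, 0 for neutral species), water activity 1,
and a(H⁺) = 10^(−pH).  One representative pore-water chemistry per zone is
applied globally: an oligotrophic oxic abyssal context, an organic-rich
sulfate-reducing margin context (near-seawater sulfate, low free sulfide)
and a methane-charged sulfate-free context.  Under these defaults the
energy yields per g C are about −35.0, −2.6 and −0.8 kJ (g C)⁻¹ — the
ordering |ΔG(aerobic)| > |ΔG(sulfate)| > |ΔG(methanogenesis)| that drives
the zone-ordered power structure.  Stoichiometric element and charge
balance is checked programmatically.

## Cells and power

Cell abundance is the power law Y = b·z^m (cells per bulk cm³, z in mbsf),
constant at b·0.1^m through the bioturbated layer.  Per-cell power is
P = r·|ΔG|/Y with r = R_POC·(1 − Φ)/seconds-per-year, i.e. the dry-basis
degradation rate converted to bulk volume before division by the
(bulk-referenced) cell density — the unit-consistent choice, since measured
abundances are per bulk volume.  All cells at a node are assumed to perform
the zone's catabolism; no dormancy or maintenance threshold is modeled
(power is supply-side).  Powers are reported positive; the signed ΔG values
appear in the run manifest.

## Synthetic worlds

The generator stands in for the global forcing compilations, which are not
redistributable at desk scale.  It reproduces their statistical structure,
not their geography:

* Domains drawn to world-ocean areal targets (shelf 6.3%, margin 10.8%,
  abyss 82.9%), with water depths uniform within per-domain ranges and the
  Antarctic shelf break at 500 m south of 60° S.
* Sedimentation rate: a double-sigmoid decline with water depth
  (ω₁ = 0.08 cm yr⁻¹ rolling off at the 200-m shelf break, ω₂ = 0.002
  cm yr⁻¹ rolling off at 4000 m), with ×1.3 geometric per-cell scatter;
  Pleistocene rates are 0.9× Holocene.
* POC₀ lognormal per domain (medians 0.035 / 0.018 / 0.005 g C cm⁻³ for
  shelf / margin / abyss); Pleistocene POC₀ equals Holocene by default.
* Bioturbation coefficient declining with water depth and clipped to the
  observed global range 0.59–27 cm² yr⁻¹.
* OPD increasing with water depth and decreasing with POC₀ (mm–cm on
  shelves, metres to tens of metres in the abyss); SMT shallowing with POC₀
  (metres on shelves, hundreds of metres in the abyss); clamped so
  OPD ≤ SMT.
* Cell-abundance parameters per domain at observed orders of magnitude
  (shelf b ~ 10⁸·²–10⁹·², abyss ~ 10⁴–10⁵·⁵; m between −0.85 and −0.45,
  steeper on shelves).
* 30% of shelf cells lack Pleistocene sediment, emulating glacial
  exposure/ice cover; their columns end at the 11,700-yr isochron.

All per-cell draws come from counter-based substreams of one seed, so
results are bit-reproducible and independent of traversal order.  Default
constants were fixed once, to honor the qualitative orderings the analysis
assumes (fast/organic-rich/anoxic shelves vs slow/lean/oxygenated abyss,
the zone-ordered energy yields above, and shelf thickness large enough that
shelf columns span the Quaternary).  Passing tests on these worlds
demonstrates the internal consistency and structural behavior of the
pipeline — zone-ordered power, redox-structured areas, the
Holocene–Pleistocene shelf-area drop — not agreement with the real ocean's
printed totals, which depend on the actual forcing compilations.

## Aggregation

Horizon summaries are evaluated exactly from the closed-form column models
at each depth (or at the isochron depth for age horizons): because the
production path is analytic, no interpolation between mesh nodes is needed
and depth-wise and age-wise integrations of the same field agree to within
numerical quadrature error.  Default horizons are 25 log-spaced depths from
0.1 to 10,000 mbsf and 25 log-spaced ages from 10³ yr to 2.59 Myr.  Power
quantiles are unweighted across contributing cells (they describe spatial
variability; an area-weighted variant is available via
`RunConfig.area_weighted_quantiles`).  Budgets integrate volumes and cells
from the SWI to the basement and POC stock/degradation over the Quaternary
section only.  The default run (800 columns, 80 nodes) completes in a few
seconds on one CPU; problem sizes in the test-suite were chosen at this
desk scale throughout.

## Known limitations

* Boundary conditions are constant per epoch; no transient compaction,
  thermal structure, or the 80 °C habitability limit.
* One representative chemistry per zone; no per-cell pore-water data, no
  temperature/pressure dependence of ΔG⁰ᵣ along geothermal gradients.
* The analytic POC path ignores bioturbation's effect on POC above 0.1 m
  (quantified by the multi-G solver; both behaviors are available).
* The cell power law admits no local abundance reversals at depth.
* Synthetic geography is statistical only; no coastlines, deltas or fans
  (shelf POC stocks are therefore not comparable to real-world budgets).
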