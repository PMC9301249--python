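"""Reactive-continuum closed forms vs quadrature oracles, and the multi-G
numerical solver."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import gamma as gamma_fn

from sedpower.poc_model import (
    RCMParams,
    column_poc,
    multi_g_bins,
    om_density,
    poc_at_age,
    rpoc_at_age,
    solve_rtm_numerical,
)
from sedpower.sediment_column import (
    Epoch,
    MeshConfig,
    build_mesh,
    _solid_column,
)

from conftest import make_cell


def poc_quadrature(poc0: float, a: float, nu: float, age: float) -> float:
    """Independent oracle: ∫ om(k,0)·e^(−k·age) dk by adaptive quadrature.

    The integrable k^(ν−1) singularity at k = 0 is removed on [0, 1/a] by
    the substitution x = u^(1/ν) (x = a·k), which flattens the integrand.
    """
    s = 1.0 + age / a
    f1 = quad(
        lambda u: np.exp(-(u ** (1.0 / nu)) * s) / nu, 0, 1, epsabs=1e-15, epsrel=1e-13
    )[0]
    f2 = quad(
        lambda x: x ** (nu - 1.0) * np.exp(-x * s), 1, np.inf, epsabs=1e-16, epsrel=1e-13
    )[0]
    return poc0 * (f1 + f2) / gamma_fn(nu)


def rpoc_quadrature(poc0: float, a: float, nu: float, age: float) -> float:
    """Independent oracle: ∫ k·om(k, age) dk (no singularity for ν > 0).

    Integrated piecewise around the k·s ~ 1 peak so adaptive quadrature
    resolves every scale regime to full precision.
    """
    s = a + age
    parts = [
        quad(
            lambda k: k**nu * np.exp(-k * s),
            lo / s,
            hi / s,
            epsabs=0,
            epsrel=1e-12,
            limit=300,
        )[0]
        for lo, hi in ((0, 1), (1, 10), (10, 60))
    ]
    tail = quad(
        lambda k: k**nu * np.exp(-k * s),
        60 / s,
        np.inf,
        epsabs=1e-30,
        epsrel=1e-12,
        limit=300,
    )[0]
    return poc0 * a**nu * (sum(parts) + tail) / gamma_fn(nu)


PARAM_SWEEP = [
    (poc0, a, nu, age)
    for poc0 in (1e-4, 1e-2, 1e-1)
    for a in (10.0, 1e3, 1e6)
    for nu in (0.05, 0.125, 0.5)
    for age in (0.0, 1e4, 2.59e6)
]


class TestClosedForms:
    def test_gamma_density_normalizes_to_poc0(self):
        params = RCMParams(0.01, 100.0, 0.125)
        assert poc_quadrature(0.01, 100.0, 0.125, 0.0) == pytest.approx(
            0.01, rel=1e-8
        )
        assert poc_at_age(params, 0.0) == 0.01

    @pytest.mark.parametrize("poc0,a,nu,age", PARAM_SWEEP)
    def test_poc_matches_quadrature(self, poc0, a, nu, age):
        closed = poc_at_age(RCMParams(poc0, a, nu), age)
        assert closed == pytest.approx(poc_quadrature(poc0, a, nu, age), rel=1e-8)

    @pytest.mark.parametrize("poc0,a,nu,age", PARAM_SWEEP)
    def test_rpoc_matches_quadrature(self, poc0, a, nu, age):
        closed = rpoc_at_age(RCMParams(poc0, a, nu), age)
        assert closed == pytest.approx(rpoc_quadrature(poc0, a, nu, age), rel=1e-8)

    def test_frozen_example_values(self):
        params = RCMParams(0.01, 100.0, 0.125)
        assert poc_at_age(params, 1e4) == pytest.approx(5.616e-3, rel=1e-3)
        assert rpoc_at_age(params, 1e4) == pytest.approx(6.951e-8, rel=1e-3)

    def test_apparent_rate_constant_identity(self):
        params = RCMParams(0.02, 500.0, 0.2)
        ages = np.geomspace(1, 1e6, 20)
        kapp = rpoc_at_age(params, ages) / poc_at_age(params, ages)
        assert np.allclose(kapp, params.nu / (params.a + ages), rtol=1e-12)
        assert np.all(np.diff(kapp) < 0)

    def test_preservation_increases_with_a(self):
        assert poc_at_age(RCMParams(0.01, 1e4, 0.125), 1e5) > poc_at_age(
            RCMParams(0.01, 1e2, 0.125), 1e5
        )

    def test_density_positive_and_input_checks(self):
        params = RCMParams(0.01, 100.0, 0.125)
        ks = np.geomspace(1e-12, 1.0, 50)  # exp() underflows above k ~ 7/a
        assert np.all(om_density(ks, params, 10.0) > 0)
        with pytest.raises(ValueError):
            om_density(0.0, params)
        with pytest.raises(ValueError):
            poc_at_age(params, -1.0)
        with pytest.raises(ValueError):
            RCMParams(0.01, -5.0, 0.125)


class TestColumnPoc:
    def test_swi_flux_identity(self):
        cell = make_cell()
        mesh = build_mesh(cell)
        prof = column_poc(cell, mesh)
        assert prof.burial_flux[0] == pytest.approx(
            (1 - cell.phi0) * cell.sed_rate_holocene * cell.poc0_holocene, rel=1e-12
        )

    def test_gap_cell_profile_ends_at_holocene(self):
        cell = make_cell(has_pleistocene=False)
        mesh = build_mesh(cell)
        prof = column_poc(cell, mesh)
        old = mesh.age > 11_700 * (1 + 1e-9)
        assert np.all(prof.poc[old] == 0.0)
        assert np.all(prof.rpoc[old] == 0.0)
        assert np.all(prof.poc[~old] > 0.0)

    def test_poc_non_increasing_within_epoch(self):
        cell = make_cell()
        mesh = build_mesh(cell)
        prof = column_poc(cell, mesh)
        for epoch in (Epoch.HOLOCENE, Epoch.PLEISTOCENE):
            sel = np.array([e is epoch for e in mesh.epoch])
            if sel.sum() > 1:
                assert np.all(np.diff(prof.poc[sel]) <= 0)
                assert np.all(np.diff(prof.burial_flux[sel]) <= 0)

    def test_flux_balance_on_refined_mesh(self):
        # epoch-uniform column: the flux balance applies within a regime of
        # constant boundary conditions (the epoch switch is a forced jump)
        cell = make_cell(
            sed_rate_pleistocene=0.05, a_pleistocene=100.0, poc0_pleistocene=0.03
        )
        mesh = build_mesh(cell, MeshConfig(n_nodes=640))
        prof = column_poc(cell, mesh)
        in_q = mesh.depths <= mesh.z_quaternary_base + 1e-9
        d = mesh.depths[in_q]
        degraded = np.trapezoid(prof.rpoc[in_q] * (1 - mesh.porosity[in_q]), d) * 100.0
        lost = prof.burial_flux[0] - prof.burial_flux[np.flatnonzero(in_q)[-1]]
        assert lost == pytest.approx(degraded, rel=1e-3)


class TestMultiG:
    def test_bin_masses_telescope_to_poc0(self):
        params = RCMParams(0.01, 100.0, 0.125)
        _, mass = multi_g_bins(params, 200)
        assert mass.sum() == pytest.approx(params.poc0, rel=1e-12)
        assert np.all(mass >= 0)

    def test_analytic_limit_without_mixing(self):
        cell = make_cell(db=0.0)
        mesh = build_mesh(cell)
        num = solve_rtm_numerical(cell, mesh, nk=200, db=0.0)
        ages = _solid_column(mesh.depths, cell.phi0, cell.c0) / (
            (1 - cell.phi0) * cell.sed_rate_holocene / 100.0
        )
        exact = poc_at_age(
            RCMParams(cell.poc0_holocene, cell.a_holocene, cell.nu), ages
        )
        below = mesh.depths > 0.1
        assert np.all(np.abs(num.poc[below] - exact[below]) / exact[below] < 0.01)

    def test_mixing_deepens_fresh_poc(self):
        cell = make_cell()
        mesh = build_mesh(cell)
        no_mix = solve_rtm_numerical(cell, mesh, nk=100, db=0.0)
        mixed = solve_rtm_numerical(cell, mesh, nk=100, db=10.0)
        i = int(np.argmin(np.abs(mesh.depths - 0.05)))
        assert mixed.poc[i] > no_mix.poc[i]

    def test_nk_floor(self):
        with pytest.raises(ValueError):
            multi_g_bins(RCMParams(0.01, 100.0, 0.125), 5)
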