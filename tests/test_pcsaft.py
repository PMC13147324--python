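"""Equation-of-state correctness: limits, oracles, derivative consistency."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracle_pcsaft import association_mixture, hc_disp_pure
from saftsol.constants import K_B, N_A
from saftsol.parameters import PureComponentParams
from saftsol.pcsaft import (
    MixtureState,
    PackingError,
    _a_res,
    _a_res_terms,
    _site_fractions,
    effective_diameter,
    helmholtz_residual,
    ln_fugacity_coefficients,
    activity_coefficients,
    pack,
    pressure,
    solve_density,
    solve_site_fractions,
)

Z0 = np.zeros((1, 1))
Z2 = np.zeros((2, 2))


def _rho_number(components, x, eta, T):
    """Number density (molecules/A^3) at a target packing fraction."""
    p = pack(components)
    d = p.sigma * (1.0 - 0.12 * np.exp(-3.0 * p.u / T))
    return eta / (np.pi / 6.0 * np.sum(np.asarray(x) * p.m * d**3))


def _comp(**kw):
    base = dict(
        id="X", name="x", m_seg=3.0, sigma=3.5, u_kB=250.0,
        eps_AB_kB=0.0, kappa_AB=0.0, assoc_scheme="none", Mw=100.0,
    )
    base.update(kw)
    return PureComponentParams(**base)


class TestEffectiveDiameter:
    def test_zero_dispersion_gives_088_sigma(self):
        c = _comp(sigma=3.0, u_kB=1e-12)
        assert effective_diameter(c, 300.0) == pytest.approx(0.88 * 3.0, rel=1e-9)

    def test_high_temperature_limit(self):
        c = _comp(sigma=3.0, u_kB=300.0)
        assert effective_diameter(c, 1e9) == pytest.approx(0.88 * 3.0, rel=1e-6)

    def test_ibuprofen_value(self, ibu):
        # independent scalar evaluation of the closed form
        expected = 3.33 * (1.0 - 0.12 * math.exp(-3.0 * 295.4 / 298.15))
        assert effective_diameter(ibu, 298.15) == pytest.approx(expected, rel=1e-14)

    def test_bounds(self, db):
        for cid in ("IBU", "WAT", "TMP"):
            c = db.component(cid)
            d = effective_diameter(c, 298.15)
            assert 0.88 * c.sigma <= d < c.sigma


class TestHelmholtzResidual:
    def test_ideal_gas_limit(self):
        c = _comp()
        # a_res vanishes linearly in rho: halving the density halves a_res
        a1 = _a_res(pack([c]), np.array([1.0]), 300.0, 1e-12, Z0)
        a2 = _a_res(pack([c]), np.array([1.0]), 300.0, 1e-14, Z0)
        assert abs(a1) < 1e-8
        assert abs(a2) < 1e-10
        assert a2 == pytest.approx(a1 / 100.0, rel=1e-3)

    def test_indistinguishable_components(self, ibu):
        """Splitting one substance into two identical pseudo-components at
        any ratio must not change a_res."""
        twin = _comp(
            id="IBU2", m_seg=ibu.m_seg, sigma=ibu.sigma, u_kB=ibu.u_kB,
            eps_AB_kB=ibu.eps_AB_kB, kappa_AB=ibu.kappa_AB,
            assoc_scheme=ibu.assoc_scheme, Mw=ibu.Mw,
        )
        T = 320.0
        rho = _rho_number([ibu], [1.0], 0.35, T)
        a_pure = _a_res(pack([ibu]), np.array([1.0]), T, rho, Z0)
        for split in (0.25, 0.5, 0.9):
            a_mix = _a_res(
                pack([ibu, twin]), np.array([split, 1.0 - split]), T, rho, Z2
            )
            assert a_mix == pytest.approx(a_pure, rel=1e-12)

    def test_breakdown_sums_and_assoc_vanishes(self, db):
        comps = [db.component("TMP"), db.component("HEX")]
        T = 310.0
        rho_number = _rho_number(comps, [0.4, 0.6], 0.4, T)
        state = MixtureState(
            components=comps, x=[0.4, 0.6], T=T, rho=rho_number * 1e30 / N_A
        )
        bd = helmholtz_residual(state)
        assert bd.a_res == pytest.approx(bd.a_hc + bd.a_disp + bd.a_assoc, abs=1e-15)
        assert bd.a_assoc == 0.0

    def test_packing_error(self, ibu):
        with pytest.raises(PackingError):
            _a_res(pack([ibu]), np.array([1.0]), 300.0,
                   _rho_number([ibu], [1.0], 0.75, 300.0), Z0)

    @pytest.mark.parametrize("cid", ["IBU", "PCM", "TMP", "CIN"])
    def test_pure_hc_disp_matches_independent_transcription(self, db, cid):
        c = db.component(cid)
        T = 330.0
        for eta in (0.05, 0.2, 0.45):
            rho = _rho_number([c], [1.0], eta, T)
            a_hc, a_disp, _ = _a_res_terms(pack([c]), np.array([1.0]), T, rho, Z0)
            o_hc, o_disp = hc_disp_pure(c.m_seg, c.sigma, c.u_kB, T, rho)
            assert float(a_hc) == pytest.approx(o_hc, rel=1e-12)
            assert float(a_disp) == pytest.approx(o_disp, rel=1e-12)

    def test_association_matches_brute_force(self, ibu, ethanol):
        T = 298.15
        x = [0.3, 0.7]
        rho = _rho_number([ibu, ethanol], x, 0.4, T)
        _, _, a_assoc = _a_res_terms(pack([ibu, ethanol]), np.array(x), T, rho, Z2)
        dicts = [
            dict(m=c.m_seg, sigma=c.sigma, u=c.u_kB, eps=c.eps_AB_kB, kappa=c.kappa_AB)
            for c in (ibu, ethanol)
        ]
        o_assoc, _, _, resid = association_mixture(dicts, x, T, rho)
        assert resid < 1e-12
        assert float(a_assoc) == pytest.approx(o_assoc, rel=1e-9)

    def test_kij_zero_reproduces_combining_rule(self, ibu, ethanol):
        """k_ij enters only the cross dispersion energy; k=0 equals passing
        no matrix at all."""
        T, x = 300.0, np.array([0.5, 0.5])
        rho = _rho_number([ibu, ethanol], x, 0.35, T)
        p = pack([ibu, ethanol])
        assert _a_res(p, x, T, rho, Z2) == _a_res(p, x, T, rho, np.zeros((2, 2)))
        a_k = _a_res(p, x, T, rho, np.array([[0.0, 0.02], [0.02, 0.0]]))
        assert a_k != _a_res(p, x, T, rho, Z2)

    def test_smooth_over_packing_range_all_pairs(self, db):
        """a_res stays finite for every bundled drug-solvent pair across the
        liquid packing range and 278-373 K."""
        from saftsol.parameters import load_bundled_apis, load_bundled_solvents

        etas = np.linspace(0.01, 0.6, 13)
        for api in load_bundled_apis():
            for solv in load_bundled_solvents():
                comps = [api, solv]
                p = pack(comps)
                for T in (278.15, 373.15):
                    rho = _rho_number(comps, [0.3, 0.7], etas, T)
                    a = _a_res(p, np.array([0.3, 0.7]), T, rho, Z2)
                    assert np.all(np.isfinite(a)), (api.id, solv.id, T)


class TestSiteFractions:
    def test_all_delta_zero_gives_unity(self, db):
        comps = [db.component("TMP"), db.component("HEX")]
        rho = _rho_number(comps, [0.5, 0.5], 0.3, 300.0)
        state = MixtureState(
            components=comps, x=[0.5, 0.5], T=300.0, rho=rho * 1e30 / N_A
        )
        sf = solve_site_fractions(state)
        assert np.all(sf.X == 1.0)

    def test_pure_2b_closed_form(self):
        """For a pure 2B fluid, X solves rhoDelta*X^2 + X - 1 = 0; at
        rho*Delta = 2 the root is exactly 1/2."""
        delta = np.array([[3.7]])
        rho = 2.0 / 3.7
        XA, XB = _site_fractions(np.array([1.0]), rho, delta)
        assert float(XA[0]) == pytest.approx(0.5, abs=1e-11)
        assert float(XB[0]) == pytest.approx(0.5, abs=1e-11)

    def test_binary_mixture_balance_and_oracle(self, ibu, water):
        T = 298.15
        x = [0.05, 0.95]
        rho = _rho_number([ibu, water], x, 0.42, T)
        state = MixtureState(
            components=[ibu, water], x=x, T=T, rho=rho * 1e30 / N_A
        )
        sf = solve_site_fractions(state)
        dicts = [
            dict(m=c.m_seg, sigma=c.sigma, u=c.u_kB, eps=c.eps_AB_kB, kappa=c.kappa_AB)
            for c in (ibu, water)
        ]
        _, XA, XB, _ = association_mixture(dicts, x, T, rho)
        np.testing.assert_allclose(sf.X[:, 0], XA, rtol=1e-9)
        np.testing.assert_allclose(sf.X[:, 1], XB, rtol=1e-9)
        assert np.all(sf.X > 0) and np.all(sf.X <= 1)
        # pure-2B symmetry: A and B sites are equivalent here
        np.testing.assert_allclose(sf.X[:, 0], sf.X[:, 1], rtol=1e-10)


class TestPressure:
    def test_ideal_gas_limit(self, ethanol):
        rho_mol = 1e-6  # mol/m^3
        state = MixtureState(components=[ethanol], x=[1.0], T=300.0, rho=rho_mol)
        P, Z = pressure(state)
        assert Z == pytest.approx(1.0, abs=1e-8)
        assert P == pytest.approx(rho_mol * N_A * K_B * 300.0, rel=1e-8)

    def test_temperature_proportionality_at_low_density(self, acetone):
        s1 = MixtureState(components=[acetone], x=[1.0], T=300.0, rho=1e-4)
        s2 = MixtureState(components=[acetone], x=[1.0], T=600.0, rho=1e-4)
        assert pressure(s2)[0] == pytest.approx(2.0 * pressure(s1)[0], rel=1e-3)

    def test_Z_matches_finite_difference(self, ibu, ethanol):
        T, x = 310.0, np.array([0.2, 0.8])
        comps = [ibu, ethanol]
        p = pack(comps)
        for eta in (0.1, 0.3, 0.5):
            rho = _rho_number(comps, x, eta, T)
            state = MixtureState(
                components=comps, x=x, T=T, rho=rho * 1e30 / N_A
            )
            _, Z = pressure(state)
            h = 1e-6
            a_p = float(np.real(_a_res(p, x, T, rho * (1 + h), Z2)))
            a_m = float(np.real(_a_res(p, x, T, rho * (1 - h), Z2)))
            Z_fd = 1.0 + (a_p - a_m) / (2.0 * h)
            assert Z == pytest.approx(Z_fd, rel=1e-6)


class TestDensitySolver:
    def test_vapor_ideal_gas(self, acetone):
        rho = solve_density([acetone], [1.0], 400.0, 100.0, "vapor")
        from saftsol.constants import R

        assert rho == pytest.approx(100.0 / (R * 400.0), rel=0.01)

    def test_pressure_round_trip(self, ethanol):
        for P in (1e3, 1e5, 1e6, 5e6):
            rho = solve_density([ethanol], [1.0], 298.15, P, "liquid")
            state = MixtureState(components=[ethanol], x=[1.0], T=298.15, rho=rho)
            assert pressure(state)[0] == pytest.approx(P, rel=1e-9)

    def test_liquid_root_denser_than_vapor(self, ethanol):
        T, P = 298.15, 101325.0
        liq = solve_density([ethanol], [1.0], T, P, "liquid")
        vap = solve_density([ethanol], [1.0], T, P, "vapor")
        assert liq > 100 * vap

    def test_invalid_phase(self, ethanol):
        with pytest.raises(ValueError):
            solve_density([ethanol], [1.0], 300.0, 1e5, "plasma")


class TestFugacityCoefficients:
    def test_ideal_gas_limit(self, acetone, ethanol):
        lnphi = ln_fugacity_coefficients(
            [acetone, ethanol], [0.5, 0.5], 450.0, 1.0, "vapor"
        )
        assert np.all(np.abs(lnphi) < 1e-5)

    def test_identical_binary_symmetry(self, ibu):
        twin = _comp(
            id="IBU2", m_seg=ibu.m_seg, sigma=ibu.sigma, u_kB=ibu.u_kB,
            eps_AB_kB=ibu.eps_AB_kB, kappa_AB=ibu.kappa_AB,
            assoc_scheme="2B", Mw=ibu.Mw,
        )
        for x1 in (0.1, 0.5, 0.8):
            lnphi = ln_fugacity_coefficients(
                [ibu, twin], [x1, 1.0 - x1], 400.0, 101325.0, "liquid"
            )
            assert lnphi[0] == pytest.approx(lnphi[1], abs=1e-10)

    def test_composition_derivatives_match_finite_difference(self, ibu, ethanol):
        """The complex-step composition gradient of a_res agrees with
        centered finite differences (the dual-route derivative check)."""
        comps = [ibu, ethanol]
        p = pack(comps)
        T = 310.0
        x = np.array([0.25, 0.75])
        rho = _rho_number(comps, x, 0.45, T)
        h = 1e-100
        hfd = 1e-6
        for i in range(2):
            xc = x.astype(complex)
            xc[i] += 1j * h
            d_cs = np.imag(_a_res(p, xc, T, rho, Z2)) / h
            xp, xm = x.copy(), x.copy()
            xp[i] += hfd
            xm[i] -= hfd
            d_fd = (
                float(np.real(_a_res(p, xp, T, rho, Z2)))
                - float(np.real(_a_res(p, xm, T, rho, Z2)))
            ) / (2 * hfd)
            assert d_cs == pytest.approx(d_fd, rel=1e-6)


class TestActivityCoefficients:
    def test_purity_normalization(self, ibu, ethanol):
        gamma = activity_coefficients([ibu, ethanol], [1.0, 0.0], 360.0)
        assert gamma[0] == pytest.approx(1.0, abs=1e-8)

    def test_identical_binary_is_ideal(self, ethanol):
        twin = _comp(
            id="EtOH2", m_seg=ethanol.m_seg, sigma=ethanol.sigma,
            u_kB=ethanol.u_kB, eps_AB_kB=ethanol.eps_AB_kB,
            kappa_AB=ethanol.kappa_AB, assoc_scheme="2B", Mw=ethanol.Mw,
        )
        for x1 in (0.2, 0.5, 0.9):
            gamma = activity_coefficients([ethanol, twin], [x1, 1 - x1], 298.15)
            np.testing.assert_allclose(gamma, 1.0, atol=1e-9)

    def test_gibbs_duhem(self, ibu, ethanol):
        """sum_i x_i dln(gamma_i)/dx1 = 0 at fixed T, P."""
        T = 298.15
        h = 1e-4
        for x1 in (0.1, 0.3, 0.6):
            lg_p = np.log(
                activity_coefficients([ibu, ethanol], [x1 + h, 1 - x1 - h], T)
            )
            lg_m = np.log(
                activity_coefficients([ibu, ethanol], [x1 - h, 1 - x1 + h], T)
            )
            slopes = (lg_p - lg_m) / (2 * h)
            gd = x1 * slopes[0] + (1 - x1) * slopes[1]
            assert abs(gd) < 1e-5


@st.composite
def random_binary_state(draw):
    def comp(i, associating):
        return PureComponentParams(
            id=f"H{i}", name="h", Mw=100.0,
            m_seg=draw(st.floats(1.0, 10.0)),
            sigma=draw(st.floats(2.9, 4.0)),
            u_kB=draw(st.floats(150.0, 400.0)),
            eps_AB_kB=draw(st.floats(500.0, 3000.0)) if associating else 0.0,
            kappa_AB=draw(st.floats(0.005, 0.05)) if associating else 0.0,
            assoc_scheme="2B" if associating else "none",
        )

    c1 = comp(1, draw(st.booleans()))
    c2 = comp(2, draw(st.booleans()))
    x1 = draw(st.floats(0.05, 0.95))
    T = draw(st.floats(250.0, 500.0))
    eta = draw(st.floats(0.05, 0.55))
    return [c1, c2], np.array([x1, 1 - x1]), T, eta


class TestDerivativeProperty:
    @settings(max_examples=12, deadline=None, derandomize=True)
    @given(random_binary_state())
    def test_density_and_composition_derivatives(self, state):
        comps, x, T, eta = state
        p = pack(comps)
        rho = _rho_number(comps, x, eta, T)
        # density derivative
        h = 1e-6
        a0 = float(np.real(_a_res(p, x, T, rho, Z2)))
        dadr_cs = np.imag(_a_res(p, x, T, rho * (1 + 1j * 1e-100), Z2)) / 1e-100
        dadr_fd = (
            float(np.real(_a_res(p, x, T, rho * (1 + h), Z2)))
            - float(np.real(_a_res(p, x, T, rho * (1 - h), Z2)))
        ) / (2 * h)
        assert dadr_cs == pytest.approx(dadr_fd, rel=1e-6, abs=1e-10 * max(1, abs(a0)))
        # composition derivative of component 0
        xc = x.astype(complex)
        xc[0] += 1j * 1e-100
        d_cs = np.imag(_a_res(p, xc, T, rho, Z2)) / 1e-100
        xp, xm = x.copy(), x.copy()
        xp[0] += h
        xm[0] -= h
        d_fd = (
            float(np.real(_a_res(p, xp, T, rho, Z2)))
            - float(np.real(_a_res(p, xm, T, rho, Z2)))
        ) / (2 * h)
        assert d_cs == pytest.approx(d_fd, rel=1e-6, abs=1e-10 * max(1, abs(a0)))
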