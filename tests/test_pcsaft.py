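import math

import numpy as np
import pytest

from asdkit.core import convert_composition
from asdkit.pcsaft import (
    _CSTEP,
    KijModel,
    Mixture,
    PcSaftParams,
    _GammaTracker,
    activity_coefficients,
    ideal_solubility,
    sle_solubility,
    sle_temperature,
)


@pytest.fixture(scope="module")
def ibu_mix(pcsaft_params):
    return Mixture([pcsaft_params["IBU"], pcsaft_params["KOLVA64"]])


class TestHelmholtzLimits:
    def test_hard_chain_reduces_to_carnahan_starling(self):
        # m = 1, negligible dispersion: Z must match the CS closed form
        p = PcSaftParams(name="hs", m_seg=1.0, sigma=3.0, eps_k=1e-8)
        mix = Mixture([p])
        for eta in (0.1, 0.3, 0.5):
            rho = mix.eta_to_rho(1000.0, eta, [1.0])
            Z = float(mix.compressibility(1000.0, rho, [1.0])[0])
            Z_cs = 1 + (4 * eta - 2 * eta**2) / (1 - eta) ** 3
            assert Z == pytest.approx(Z_cs, rel=1e-6)

    def test_ideal_gas_limit(self, ibu_mix):
        # a_res vanishes linearly in rho (with a large polymeric prefactor)
        a20 = float(np.real(ibu_mix.a_res(350.0, 1e-20, [0.6, 0.4])[0]))
        a18 = float(np.real(ibu_mix.a_res(350.0, 1e-18, [0.6, 0.4])[0]))
        Z = float(ibu_mix.compressibility(350.0, np.array([1e-20]),
                                          [0.6, 0.4])[0])
        assert a20 == pytest.approx(0.0, abs=1e-9)
        assert a18 == pytest.approx(100.0 * a20, rel=1e-2)  # linear decay
        assert Z == pytest.approx(1.0, abs=1e-9)

    def test_association_term_exactly_zero_without_kappa(self):
        p = PcSaftParams(name="x", m_seg=2.0, sigma=3.5, eps_k=250.0,
                         eps_assoc_k=1000.0, kappa_assoc=0.0, N_assoc=2.0)
        mix = Mixture([p])
        rho = mix.eta_to_rho(300.0, 0.4, [1.0])
        _, _, a_assoc = mix.a_res(300.0, rho, [1.0], parts=True)
        assert float(np.real(a_assoc[0])) == 0.0
        assert not mix.has_assoc

    def test_induced_association_active_for_mixed_pair(self, pcsaft_params):
        # the polymer has no self-association energy, yet cross terms with
        # the acid switch on (Wolbach-Sandler arithmetic mean)
        mix = Mixture([pcsaft_params["IBU"], pcsaft_params["KOLVA64"]])
        assert mix.assoc_pair[0, 1] and mix.assoc_pair[1, 0]
        assert mix.assoc_pair[0, 0] and not mix.assoc_pair[1, 1]


class TestDerivativeConsistency:
    def test_density_derivative_matches_central_difference(self, ibu_mix):
        # Z = 1 + rho d(a)/d(rho): complex-step route vs central differences
        rng = np.random.default_rng(1234)
        for _ in range(10):
            x1 = rng.uniform(0.05, 0.95)
            eta = rng.uniform(0.15, 0.55)
            T = rng.uniform(280.0, 400.0)
            x = np.array([x1, 1 - x1])
            rho = ibu_mix.eta_to_rho(T, eta, x)
            cs = np.imag(ibu_mix.a_res(T, rho + 1j * _CSTEP, x)[0]) / _CSTEP
            h = rho * 1e-6
            fd = (np.real(ibu_mix.a_res(T, rho + h, x)[0])
                  - np.real(ibu_mix.a_res(T, rho - h, x)[0])) / (2 * h)
            assert cs == pytest.approx(fd, rel=1e-6)

    def test_composition_derivative_matches_central_difference(self, ibu_mix):
        T, eta = 350.0, 0.45
        x = np.array([0.7, 0.3])
        rho = ibu_mix.eta_to_rho(T, eta, x)
        for i in range(2):
            xc = x.astype(complex)
            xc[i] += 1j * _CSTEP
            cs = np.imag(ibu_mix.a_res(T, rho, xc)[0]) / _CSTEP
            h = 1e-6
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            fd = (np.real(ibu_mix.a_res(T, rho, xp)[0])
                  - np.real(ibu_mix.a_res(T, rho, xm)[0])) / (2 * h)
            assert cs == pytest.approx(fd, rel=1e-6)


class TestDensity:
    def test_liquid_root_is_reproducible_and_physical(self, pcsaft_params):
        mix = Mixture([pcsaft_params["IBU"]])
        r1 = mix.density(298.15, 1e5, [1.0])
        r2 = mix.density(298.15, 1e5, [1.0])
        assert r1 == r2  # deterministic bracketing
        eta = float(mix.rho_to_eta(298.15, r1, [1.0]))
        assert 0.3 < eta < 0.6

    def test_pressure_monotone_in_density_near_liquid_root(self, pcsaft_params):
        mix = Mixture([pcsaft_params["IBU"]])
        rho0 = mix.density(298.15, 1e5, [1.0])
        P = [float(mix.pressure(298.15, rho0 * f, [1.0])[0])
             for f in (0.999, 1.0, 1.001)]
        assert P[0] < P[1] < P[2]

    def test_raising_pressure_raises_packing(self, pcsaft_params):
        mix = Mixture([pcsaft_params["IBU"]])
        etas = [float(mix.rho_to_eta(298.15, mix.density(298.15, P, [1.0]),
                                     [1.0]))
                for P in (1e5, 1e7, 5e7)]
        assert etas[0] < etas[1] < etas[2]


class TestActivityCoefficients:
    def test_unity_at_pure_limit_exactly(self, ibu_mix):
        g = activity_coefficients(ibu_mix, 350.0, x=[1.0, 0.0])
        assert g[0] == 1.0

    def test_identical_components_are_indistinguishable(self, pcsaft_params):
        mix = Mixture([pcsaft_params["IBU"], pcsaft_params["IBU"]])
        g = activity_coefficients(mix, 330.0, x=[0.3, 0.7])
        assert g[0] == pytest.approx(1.0, abs=1e-9)
        assert g[1] == pytest.approx(1.0, abs=1e-9)

    def test_gibbs_duhem_along_composition_path(self, ibu_mix):
        # sum_i x_i d(ln gamma_i)/dx = 0 at constant T, P; derivatives by a
        # fourth-order stencil, residual normalized by the term magnitudes
        tracker = _GammaTracker(ibu_mix)
        T, h = 350.0, 1e-3

        def lng(x1):
            return tracker.ln_gammas(T, np.array([x1, 1 - x1]))

        for x1 in (0.3, 0.5, 0.7, 0.9):
            v = [lng(x1 + k * h) for k in (-2, -1, 1, 2)]
            d = (v[0] - 8 * v[1] + 8 * v[2] - v[3]) / (12 * h)
            resid = x1 * d[0] + (1 - x1) * d[1]
            scale = abs(x1 * d[0]) + abs((1 - x1) * d[1])
            assert abs(resid) / scale < 1e-5


class TestSLE:
    def test_ideal_solubility_hand_value(self, ibu):
        # exp[-dH/(RT)(1-T/Tm) - dCp/R (1 - Tm/T + ln(Tm/T))] at 298.15 K
        assert ideal_solubility(ibu, 298.15) == pytest.approx(0.266, abs=1e-3)
        assert ideal_solubility(ibu, ibu.Tm) == 1.0

    def test_melting_point_limit(self, ibu_mix, ibu):
        x, K = sle_solubility(ibu_mix, ibu, ibu.Tm)
        assert x == 1.0 and K == 1.0
        assert sle_temperature(ibu_mix, ibu, 1.0) == ibu.Tm

    def test_fixed_point_equals_bisection_oracle(self, pcsaft_params, ibu,
                                                 compounds):
        for poly in ("KOLVA64", "HPMCAS"):
            mix = Mixture([pcsaft_params["IBU"], pcsaft_params[poly]])
            x_fp, _ = sle_solubility(mix, ibu, 320.0)
            x_bi, _ = sle_solubility(mix, ibu, 320.0, method="bisection")
            assert x_fp == pytest.approx(x_bi, abs=1e-8)

    def test_saturation_temperature_inverts_solubility(self, ibu_mix, ibu,
                                                       compounds):
        poly = compounds["KOLVA64"]
        x = convert_composition(0.6, "w", "x", ibu, poly)
        T = sle_temperature(ibu_mix, ibu, x)
        x_back, _ = sle_solubility(ibu_mix, ibu, T)
        assert x_back == pytest.approx(x, rel=1e-5)

    def test_curve_reaches_melting_point_for_all_polymers(self, pcsaft_params,
                                                          ibu):
        for poly in ("KOLVA64", "KOL17PF", "HPMCAS", "EPO"):
            for kij in (0.0, 0.05):
                mix = Mixture([pcsaft_params["IBU"], pcsaft_params[poly]],
                              kij=kij)
                assert sle_temperature(mix, ibu, 1.0) == ibu.Tm


class TestKijModel:
    def test_temperature_linearity(self):
        k = KijModel(k_int=0.05, k_slope=1e-4)
        assert k(300.0) == pytest.approx(0.05 + 0.03)
        assert KijModel(k_int=0.05)(300.0) == 0.05

    def test_kij_shifts_cross_dispersion_only(self, pcsaft_params):
        m0 = Mixture([pcsaft_params["IBU"], pcsaft_params["KOLVA64"]], kij=0.0)
        m1 = Mixture([pcsaft_params["IBU"], pcsaft_params["KOLVA64"]],
                     kij=0.05)
        T, eta = 350.0, 0.45
        x = np.array([0.7, 0.3])
        rho = m0.eta_to_rho(T, eta, x)
        # pure-component states are unaffected
        rho_p = m0.eta_to_rho(T, eta, [1.0, 0.0])
        a0 = float(np.real(m0.a_res(T, rho_p, [1.0, 0.0])[0]))
        a1 = float(np.real(m1.a_res(T, rho_p, [1.0, 0.0])[0]))
        assert a0 == pytest.approx(a1, rel=1e-12)
        # mixed states are
        b0 = float(np.real(m0.a_res(T, rho, x)[0]))
        b1 = float(np.real(m1.a_res(T, rho, x)[0]))
        assert b0 != pytest.approx(b1, rel=1e-9)
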