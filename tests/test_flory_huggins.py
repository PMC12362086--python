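import numpy as np
import pytest

from asdkit.core import MPDDataset, convert_composition
from asdkit.flory_huggins import (
    FHModel,
    binodal,
    binodal_gridsearch,
    chi_per_point,
    chi_points,
    chi_slope_fit,
    chi_temperature_fit,
    critical_point,
    gibbs_curve,
    sle_curve,
    sle_temperature,
    spinodal_phis,
    volume_ratio,
)
from asdkit.synthetic_data import SyntheticSpec, generate_mpd

from conftest import make_pair


class TestVolumeRatio:
    def test_tabulated_pairs(self, compounds):
        ibu = compounds["IBU"]
        assert volume_ratio(ibu, compounds["KOLVA64"]) == pytest.approx(
            286.69, abs=0.01)
        assert volume_ratio(ibu, compounds["KOL17PF"]) == pytest.approx(
            48.13, abs=0.01)

    def test_identical_compounds_give_unity(self, ibu):
        assert volume_ratio(ibu, ibu) == 1.0


class TestChiExtraction:
    def test_zero_depression_limit(self, ibu, kolva64):
        # at T_end = Tm the depression term vanishes and chi is the pure
        # combinatorial correction
        w = 0.6
        m = volume_ratio(ibu, kolva64)
        phi = convert_composition(w, "w", "phi", ibu, kolva64)
        pp = 1 - phi
        cp = chi_per_point(w, ibu.Tm, ibu, kolva64)
        expected = -(np.log(phi) + (1 - 1 / m) * pp) / pp**2
        assert cp.chi == pytest.approx(expected, rel=1e-12)

    def test_round_trip_through_sle_relation(self, ibu, kolva64):
        model = FHModel(api=ibu, poly=kolva64, A=0.65, B=0.0)
        w = 0.45
        phi = convert_composition(w, "w", "phi", ibu, kolva64)
        T = sle_temperature(model, phi)
        assert chi_per_point(w, T, ibu, kolva64).chi == pytest.approx(
            0.65, abs=1e-10)

    def test_pure_drug_rejected(self, ibu, kolva64):
        with pytest.raises(ValueError):
            chi_per_point(1.0, 348.0, ibu, kolva64)

    def test_slope_fit_recovers_constant_chi(self, ibu, kolva64):
        for chi_true in (0.96, 0.0):
            spec = SyntheticSpec(generator="fh",
                                 params={"A": chi_true, "B": 0.0},
                                 noise_sd=0.0)
            ds = generate_mpd(spec, ibu, kolva64)
            chi, r2 = chi_slope_fit(ds, ibu, kolva64)
            assert chi == pytest.approx(chi_true, abs=1e-10)
            if chi_true != 0.0:  # r2 is undefined for an all-zero response
                assert r2 == pytest.approx(1.0, abs=1e-10)

    def test_slope_fit_rejects_degenerate_design(self, ibu, kolva64):
        ds = MPDDataset(api="IBU", polymer="KOLVA64",
                        points=[(0.5, 340.0)] * 4)
        with pytest.raises(ValueError, match="degenerate"):
            chi_slope_fit(ds, ibu, kolva64)

    def test_temperature_fit_exact_line_and_ucst_flag(self):
        from asdkit.flory_huggins import ChiPoint
        T = np.array([310.0, 325.0, 340.0, 355.0])
        pts = [ChiPoint(w_API=0.5, phi_poly=0.5, T_end=t, chi=-2.0 + 1000.0 / t)
               for t in T]
        A, B = chi_temperature_fit(pts)
        assert A == pytest.approx(-2.0, abs=1e-10)
        assert B == pytest.approx(1000.0, abs=1e-7)
        assert A < 0 and B > 0  # UCST signature

    def test_temperature_fit_needs_distinct_temperatures(self):
        from asdkit.flory_huggins import ChiPoint
        pts = [ChiPoint(0.5, 0.5, 340.0, 0.6), ChiPoint(0.6, 0.4, 340.0, 0.7)]
        with pytest.raises(ValueError):
            chi_temperature_fit(pts)


class TestSLECurve:
    def test_pure_api_limit_is_melting_point(self, ibu, kolva64):
        model = FHModel(api=ibu, poly=kolva64, A=-2.0, B=850.0)
        assert sle_temperature(model, 1.0) == ibu.Tm
        curve = sle_curve(model, [1.0], basis="phi")
        assert curve[0, 1] == ibu.Tm

    def test_exact_solution_matches_bracketed_root(self, ibu, kolva64):
        model = FHModel(api=ibu, poly=kolva64, A=-2.0, B=850.0)
        for phi in (0.2, 0.4, 0.6, 0.8, 0.95):
            assert sle_temperature(model, phi) == pytest.approx(
                sle_temperature(model, phi, method="bracket"), abs=1e-6)

    def test_ideal_long_chain_limit_against_bisection(self):
        # chi = 0, very long chain: ln(phi) + phi_p = -dH/R (1/T - 1/Tm)
        api, poly = make_pair(1e9)
        model = FHModel(api=api, poly=poly, A=0.0, B=0.0)
        from scipy.optimize import bisect
        from asdkit.core import R
        for phi in (0.3, 0.6, 0.9):
            def h(T):
                return (1 / T - 1 / api.Tm
                        + (R / api.dHfus) * (np.log(phi) + (1 - phi)))
            T_oracle = bisect(h, 100.0, api.Tm + 1.0, xtol=1e-10)
            assert sle_temperature(model, phi) == pytest.approx(
                T_oracle, abs=1e-6)

    def test_depression_monotone_for_ucst_parameters(self, ibu, kolva64):
        model = FHModel(api=ibu, poly=kolva64, A=-2.0, B=750.0)
        phis = np.linspace(0.3, 1.0, 30)
        T = [sle_temperature(model, p) for p in phis]
        assert np.all(np.diff(T) > 0)  # less drug, more depression

    def test_round_trip_with_slope_chi(self, ibu, kolva64):
        # exact synthetic data -> slope chi -> SLE curve reproduces the
        # generating temperatures
        chi_true = 0.4
        spec = SyntheticSpec(generator="fh", params={"A": chi_true, "B": 0.0},
                             noise_sd=0.0)
        ds = generate_mpd(spec, ibu, kolva64)
        chi, _ = chi_slope_fit(ds, ibu, kolva64)
        model = FHModel(api=ibu, poly=kolva64, A=chi, B=0.0)
        for (w, T_gen) in ds.points:
            phi = convert_composition(w, "w", "phi", ibu, kolva64)
            assert sle_temperature(model, phi) == pytest.approx(T_gen,
                                                                abs=1e-6)


class TestGibbsCurve:
    def test_symmetric_ideal_mixture_value(self):
        api, poly = make_pair(1.0)
        model = FHModel(api=api, poly=poly, A=0.0, B=0.0)
        g = gibbs_curve(model, 300.0, grid=np.array([0.0, 0.5, 1.0]))
        assert g.g[0] == 0.0 and g.g[2] == 0.0  # pure-component limits
        assert g.g[1] == pytest.approx(np.log(0.5))

    def test_exchange_symmetry_at_m_one(self):
        api, poly = make_pair(1.0)
        model = FHModel(api=api, poly=poly, A=0.7, B=0.0)
        grid = np.linspace(0.05, 0.95, 19)
        g = gibbs_curve(model, 300.0, grid=grid).g
        assert np.allclose(g, g[::-1], atol=1e-12)

    def test_large_chi_double_well(self):
        api, poly = make_pair(1.0)
        model = FHModel(api=api, poly=poly, A=5.0, B=0.0)
        grid = np.linspace(0.001, 0.999, 2001)
        g = gibbs_curve(model, 300.0, grid=grid).g
        # interior local maximum between two minima
        sign_changes = np.sum(np.abs(np.diff(np.sign(np.diff(g)))) > 0)
        assert sign_changes >= 3


class TestPhaseBoundaries:
    @pytest.mark.parametrize("m", [1.0, 48.13, 286.69])
    def test_critical_point_matches_closed_form(self, m):
        phi_api_c, chi_c = critical_point(m)
        # closed forms: critical polymer fraction 1/(1+sqrt(m)),
        # chi_c = (1 + 1/sqrt(m))^2 / 2
        assert 1.0 - phi_api_c == pytest.approx(1.0 / (1.0 + np.sqrt(m)),
                                                abs=1e-8)
        assert chi_c == pytest.approx(0.5 * (1.0 + 1.0 / np.sqrt(m)) ** 2,
                                      abs=1e-8)

    def test_symmetric_spinodal_collapses_at_critical_chi(self):
        lo, hi = spinodal_phis(1.0, 2.0 + 1e-12)
        assert lo == pytest.approx(0.5, abs=1e-5)
        assert hi == pytest.approx(0.5, abs=1e-5)
        assert spinodal_phis(1.0, 1.9) is None  # above critical point

    @pytest.mark.parametrize("m, chi", [(1.0, 2.5), (48.13, 0.75),
                                        (286.69, 0.60)])
    def test_binodal_matches_gridsearch_oracle(self, m, chi):
        api, poly = make_pair(m)
        model = FHModel(api=api, poly=poly, A=chi, B=0.0)
        a, b = binodal(model, 300.0)
        ao, bo = binodal_gridsearch(m, chi)
        assert a == pytest.approx(ao, abs=1e-4)
        assert b == pytest.approx(bo, abs=1e-4)

    @pytest.mark.parametrize("m, chi", [(1.0, 2.5), (48.13, 0.75),
                                        (286.69, 0.60), (286.69, 0.8)])
    def test_spinodal_nested_inside_binodal(self, m, chi):
        api, poly = make_pair(m)
        model = FHModel(api=api, poly=poly, A=chi, B=0.0)
        a, b = binodal(model, 300.0)
        s_lo, s_hi = spinodal_phis(m, chi)
        assert a <= s_lo < s_hi <= b

    def test_binodal_collapses_toward_critical_point(self):
        api, poly = make_pair(1.0)
        model = FHModel(api=api, poly=poly, A=2.0001, B=0.0)
        a, b = binodal(model, 300.0)
        assert a == pytest.approx(0.5, abs=0.02)
        assert b == pytest.approx(0.5, abs=0.02)

    def test_derivative_mode_differs_from_tangent(self):
        # the printed first-derivative-zero condition locates extrema of g,
        # not coexistence; kept for comparison only (moderate m so interior
        # extrema exist)
        api, poly = make_pair(2.0)
        model = FHModel(api=api, poly=poly, A=2.0, B=0.0)
        t = binodal(model, 300.0)
        d = binodal(model, 300.0, method="derivative")
        assert abs(t[0] - d[0]) > 1e-4

    def test_convexity_above_critical_temperature(self):
        api, poly = make_pair(48.13)
        model = FHModel(api=api, poly=poly, A=-2.0, B=850.0)
        _, chi_c = critical_point(48.13)
        T_c = model.B / (chi_c - model.A)
        grid = np.linspace(0.01, 0.99, 400)
        g_above = gibbs_curve(model, T_c + 5.0, grid=grid).g
        assert np.all(np.diff(g_above, 2) > -1e-12)  # strictly convex
        g_below = gibbs_curve(model, T_c - 5.0, grid=grid).g
        assert np.any(np.diff(g_below, 2) < 0)  # concave window opens
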