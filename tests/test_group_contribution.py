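import math

import pytest

from asdkit.group_contribution import (
    GCMethod,
    GroupInventory,
    GroupTable,
    SolubilityParams,
    bagley_distance,
    chi_from_delta,
    fedors_delta,
    hvk_delta,
    load_group_table,
    load_inventory,
    screen_pair,
)


def fedors_table(rows):
    return GroupTable(method=GCMethod.Fedors, rows=rows)


def hvk_table(rows):
    return GroupTable(method=GCMethod.HVK, rows=rows)


class TestFedors:
    def test_single_group_hand_value(self):
        t = fedors_table({"g": {"E": 40000.0, "V": 100.0}})
        sp = fedors_delta(GroupInventory("c", {"g": 1.0}), t)
        assert sp.delta_t == pytest.approx(20.0)  # sqrt(400 J/cm3)
        assert not sp.has_components

    def test_count_scaling_invariance(self):
        t = fedors_table({"g": {"E": 40000.0, "V": 100.0},
                          "h": {"E": 10000.0, "V": 30.0}})
        inv1 = GroupInventory("c", {"g": 1.0, "h": 2.0})
        inv2 = GroupInventory("c", {"g": 2.5, "h": 5.0})
        assert fedors_delta(inv1, t).delta_t == pytest.approx(
            fedors_delta(inv2, t).delta_t)

    def test_additivity_of_merged_groups(self):
        t = fedors_table({"a": {"E": 10000.0, "V": 50.0},
                          "b": {"E": 10000.0, "V": 50.0},
                          "ab": {"E": 20000.0, "V": 100.0}})
        two = fedors_delta(GroupInventory("c", {"a": 1, "b": 1}), t)
        one = fedors_delta(GroupInventory("c", {"ab": 1}), t)
        assert two.delta_t == pytest.approx(one.delta_t)

    def test_missing_group_reported(self):
        t = fedors_table({"g": {"E": 40000.0, "V": 100.0}})
        with pytest.raises(KeyError, match="absent"):
            fedors_delta(GroupInventory("c", {"nope": 1.0}), t)


class TestHVK:
    def test_single_group_dispersive_is_ratio(self):
        t = hvk_table({"g": {"Fd": 500.0, "Fp": 0.0, "Eh": 0.0, "V": 50.0}})
        sp = hvk_delta(GroupInventory("c", {"g": 1.0}), t)
        assert sp.delta_d == pytest.approx(10.0)
        assert sp.delta_t == pytest.approx(sp.delta_d)  # Fp = Eh = 0 collapse

    def test_polar_term_sums_squares_not_squared_sum(self):
        t = hvk_table({"g": {"Fd": 0.0, "Fp": 500.0, "Eh": 0.0, "V": 50.0}})
        sp = hvk_delta(GroupInventory("c", {"g": 2.0}), t)
        # sqrt(2 * 500^2)/100, not (2*500)/100
        assert sp.delta_p == pytest.approx(math.sqrt(2 * 500.0**2) / 100.0)
        assert sp.delta_p == pytest.approx(7.0711, abs=1e-4)

    def test_total_obeys_component_sum(self):
        t = hvk_table({"g": {"Fd": 420.0, "Fp": 300.0, "Eh": 8000.0, "V": 30.0}})
        sp = hvk_delta(GroupInventory("c", {"g": 1.0}), t)
        assert sp.delta_t**2 == pytest.approx(
            sp.delta_d**2 + sp.delta_p**2 + sp.delta_h**2, rel=1e-9)
        assert sp.delta_t >= max(sp.delta_d, sp.delta_p, sp.delta_h)


class TestBagley:
    def sp(self, dd, dp, dh, method=GCMethod.HVK):
        return SolubilityParams(method=method, delta_d=dd, delta_p=dp,
                                delta_h=dh,
                                delta_t=math.sqrt(dd * dd + dp * dp + dh * dh))

    def test_self_distance_zero_and_symmetry(self):
        a = self.sp(16.0, 6.0, 8.0)
        b = self.sp(18.0, 4.0, 5.0)
        assert bagley_distance(a, a) == 0.0
        assert bagley_distance(a, b) == pytest.approx(bagley_distance(b, a))

    def test_hand_value(self):
        # delta_v difference 3, delta_h difference 4 -> sqrt(4*9 + 16)
        a = self.sp(10.0, 0.0, 0.0)
        b = self.sp(13.0, 0.0, 4.0)
        assert bagley_distance(a, b) == pytest.approx(math.sqrt(52.0))
        assert bagley_distance(a, b) == pytest.approx(7.2111, abs=1e-4)

    def test_triangle_inequality(self):
        a = self.sp(16.0, 6.0, 8.0)
        b = self.sp(18.0, 4.0, 5.0)
        c = self.sp(15.0, 9.0, 11.0)
        assert bagley_distance(a, c) <= (bagley_distance(a, b)
                                         + bagley_distance(b, c) + 1e-12)

    def test_fedors_inputs_rejected(self):
        f = SolubilityParams(method=GCMethod.Fedors, delta_t=20.0)
        with pytest.raises(ValueError, match="components"):
            bagley_distance(f, f)


class TestChiFromDelta:
    def test_equal_deltas_give_zero(self):
        a = SolubilityParams(method=GCMethod.Fedors, delta_t=20.0)
        assert chi_from_delta(a, a, 298.15, 185.84) == 0.0

    def test_hand_value_ibuprofen_site_volume(self):
        a = SolubilityParams(method=GCMethod.Fedors, delta_t=21.0)
        b = SolubilityParams(method=GCMethod.Fedors, delta_t=20.0)
        # 1e6 Pa * 185.84e-6 m3/mol / (R * 298.15 K)
        assert chi_from_delta(a, b, 298.15, 185.84) == pytest.approx(
            0.0750, abs=2e-4)

    def test_scaling_in_v0_and_delta(self):
        a = SolubilityParams(method=GCMethod.Fedors, delta_t=22.0)
        b = SolubilityParams(method=GCMethod.Fedors, delta_t=20.0)
        chi1 = chi_from_delta(a, b, 300.0, 100.0)
        assert chi_from_delta(a, b, 300.0, 200.0) == pytest.approx(2 * chi1)
        a2 = SolubilityParams(method=GCMethod.Fedors, delta_t=24.0)
        assert chi_from_delta(a2, b, 300.0, 100.0) == pytest.approx(4 * chi1)


class TestScreening:
    @pytest.mark.parametrize("ddelta, verdict", [
        (5.0, "soluble"), (-5.0, "soluble"),
        (8.5, "borderline"), (-8.5, "borderline"),
        (12.0, "immiscible"),
    ])
    def test_rule_of_thumb_verdicts(self, ddelta, verdict):
        t = hvk_table({
            "a": {"Fd": 2000.0, "Fp": 0.0, "Eh": 0.0, "V": 100.0},
            "b": {"Fd": (20.0 + ddelta) * 100.0, "Fp": 0.0, "Eh": 0.0,
                  "V": 100.0},
        })
        res = screen_pair(GroupInventory("A", {"b": 1.0}),
                          GroupInventory("P", {"a": 1.0}), t, V0=100.0)
        assert res.delta_delta_t == pytest.approx(ddelta)
        assert res.verdict == verdict

    def test_bundled_tables_screen_all_pairs(self, compounds):
        api_inv = load_inventory("IBU")
        for method in GCMethod:
            table = load_group_table(method)
            d_api = (fedors_delta if method is GCMethod.Fedors else hvk_delta)(
                api_inv, table)
            assert 15.0 < d_api.delta_t < 30.0  # plausible for a small acid
            for poly in ("KOLVA64", "KOL17PF", "HPMCAS", "EPO"):
                res = screen_pair(api_inv, load_inventory(poly), table,
                                  api=compounds["IBU"])
                assert res.verdict in ("soluble", "borderline", "immiscible")
                assert res.chi_gc >= 0.0
                if method is not GCMethod.Fedors:
                    assert res.R_av >= 0.0
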