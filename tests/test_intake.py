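"""Fructose intake estimation: decomposition, imputation, partitioning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fructrisk as fr
from fructrisk.errors import (
    DomainError,
    InvalidMixError,
    UnknownFoodError,
    UnresolvedCommodityError,
)
from fructrisk.intake import build_fraction_audit

MIX = fr.SweetenerMix()  # shares 0.5/0.4/0.1, fractions 0.55/0.42/0.0


class TestDecompose:
    def test_direct_proportion(self, tiny_composition):
        recalls = pd.DataFrame(
            [("S", "F_FRUIT", 100.0)],
            columns=["subject_id", "food_id", "grams_consumed"],
        )
        out = fr.decompose(recalls, tiny_composition).set_index("commodity_id")
        assert out.loc["APPLE", "mass_g"] == pytest.approx(50.0)
        assert out.loc["OJ", "mass_g"] == pytest.approx(40.0)

    def test_empty_recalls(self, tiny_composition):
        out = fr.decompose(
            pd.DataFrame(columns=["subject_id", "food_id", "grams_consumed"]),
            tiny_composition,
        )
        assert len(out) == 0

    def test_split_records_additive(self, tiny_composition):
        one = pd.DataFrame(
            [("S", "F_FRUIT", 100.0)],
            columns=["subject_id", "food_id", "grams_consumed"],
        )
        two = pd.DataFrame(
            [("S", "F_FRUIT", 50.0), ("S", "F_FRUIT", 50.0)],
            columns=["subject_id", "food_id", "grams_consumed"],
        )
        a = fr.decompose(one, tiny_composition)
        b = fr.decompose(two, tiny_composition)
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_food_named(self, tiny_composition):
        recalls = pd.DataFrame(
            [("S", "F_NOPE", 10.0)],
            columns=["subject_id", "food_id", "grams_consumed"],
        )
        with pytest.raises(UnknownFoodError, match="F_NOPE"):
            fr.decompose(recalls, tiny_composition)

    def test_mass_conservation_per_food(self, tiny_composition):
        recalls = pd.DataFrame(
            [("S", "F_SODA", 100.0)],
            columns=["subject_id", "food_id", "grams_consumed"],
        )
        out = fr.decompose(recalls, tiny_composition)
        assert out["mass_g"].sum() <= 100.0 * (0.11 + 0.05) + 1e-12


class TestResolveFructoseFraction:
    def test_direct(self, tiny_nutrients):
        profile = {"commodity_id": "X", "fructose_per_100g": 2.4,
                   "carb_per_100g": 10.0, "family_id": None}
        frac, prov = fr.resolve_fructose_fraction(profile, tiny_nutrients)
        assert frac == pytest.approx(0.024)
        assert prov == "direct"

    def test_ratio_imputed(self, tiny_nutrients):
        oj = tiny_nutrients.set_index("commodity_id", drop=False).loc["OJ"]
        frac, prov = fr.resolve_fructose_fraction(oj, tiny_nutrients)
        # carb 10/100g scaled by orange's fructose:carb ratio 2.25/11.54
        assert frac == pytest.approx(0.10 * (2.25 / 11.54), abs=1e-12)
        assert frac == pytest.approx(0.0195, abs=5e-5)
        assert prov == "ratio_imputed"

    def test_family_zero_carb_guard(self):
        ref = pd.DataFrame(
            {
                "commodity_id": ["FAM"],
                "fructose_per_100g": [5.0],
                "carb_per_100g": [0.0],
            }
        )
        profile = {"commodity_id": "X", "fructose_per_100g": np.nan,
                   "carb_per_100g": 10.0, "family_id": "FAM"}
        with pytest.raises(UnresolvedCommodityError):
            fr.resolve_fructose_fraction(profile, ref)

    def test_no_route(self, tiny_nutrients):
        profile = {"commodity_id": "X", "fructose_per_100g": np.nan,
                   "carb_per_100g": 10.0, "family_id": None}
        with pytest.raises(UnresolvedCommodityError):
            fr.resolve_fructose_fraction(profile, tiny_nutrients)


class TestPartitionCornSweetener:
    def test_weighted_partition(self):
        # 0.5*55 + 0.4*42 + 0.1*0 = 44.3 g per 100 g
        assert fr.partition_corn_sweetener(100.0, MIX) == pytest.approx(44.3)

    def test_zero_mass(self):
        assert fr.partition_corn_sweetener(0.0, MIX) == 0.0

    def test_single_component(self):
        mix = fr.SweetenerMix(share_hfcs55=1.0, share_hfcs42=0.0, share_corn_syrup=0.0)
        assert fr.partition_corn_sweetener(10.0, mix) == pytest.approx(5.5)

    def test_bad_shares(self):
        with pytest.raises(InvalidMixError):
            fr.SweetenerMix(share_hfcs55=0.7, share_hfcs42=0.4, share_corn_syrup=0.1)

    def test_negative_mass(self):
        with pytest.raises(DomainError):
            fr.partition_corn_sweetener(-1.0, MIX)


class TestAddedBoundFructose:
    @pytest.mark.parametrize(
        "sucrose,expected", [(20.0, 10.0), (0.0, 0.0), (99.86, 49.93)]
    )
    def test_half_of_sucrose(self, sucrose, expected):
        assert fr.added_bound_fructose(sucrose) == pytest.approx(expected)

    def test_negative(self):
        with pytest.raises(DomainError):
            fr.added_bound_fructose(-0.1)


class TestNaturalBoundUnderestimate:
    def test_hand_arithmetic(self):
        assert fr.natural_bound_underestimate(50, 20, 10, 0.5) == pytest.approx(5.0)

    def test_clamps_negative_remainder(self):
        assert fr.natural_bound_underestimate(100, 100, 0, 0.2653) == 0.0
        assert fr.natural_bound_underestimate(10, 50, 10, 0.2653) == 0.0

    def test_ratio_domain(self):
        with pytest.raises(DomainError):
            fr.natural_bound_underestimate(100, 50, 10, 1.2)


class TestEstimateIntakes:
    def _run(self, recalls, comp, nut, energy):
        return fr.estimate_intakes(recalls, comp, nut, MIX, energy)

    def test_hand_fixture_oracle(
        self, tiny_recalls, tiny_composition, tiny_nutrients, tiny_energy
    ):
        """Components match an explicit spreadsheet-style calculation."""
        intakes, audit = self._run(
            tiny_recalls, tiny_composition, tiny_nutrients, tiny_energy
        )
        out = intakes.set_index("subject_id")
        oj_frac = 0.10 * (2.25 / 11.54)
        s1_nat = 200 * (0.5 * 0.06 + 0.4 * oj_frac) + 100 * 0.05 * oj_frac
        s1_add_unb = 100 * 0.11 * (0.5 * 0.55 + 0.4 * 0.42)
        assert out.loc["S1", "natural_unbound_g"] == pytest.approx(s1_nat, abs=1e-9)
        assert out.loc["S1", "added_unbound_g"] == pytest.approx(s1_add_unb, abs=1e-9)
        assert out.loc["S1", "added_bound_g"] == pytest.approx(0.0, abs=1e-12)
        s2_nat = 150 * 0.2 * 0.06
        s2_bound = 0.5 * 150 * 0.3 * 1.0
        assert out.loc["S2", "natural_unbound_g"] == pytest.approx(s2_nat, abs=1e-9)
        assert out.loc["S2", "added_bound_g"] == pytest.approx(s2_bound, abs=1e-9)
        assert out.loc["S2", "added_unbound_g"] == pytest.approx(0.0, abs=1e-12)
        # %energy at 4 kcal/g
        assert out.loc["S2", "total_pct_energy"] == pytest.approx(
            100 * 4 * (s2_nat + s2_bound) / 1500.0, abs=1e-9
        )
        assert set(audit["provenance"]) == {"direct", "ratio_imputed"}

    def test_pure_sucrose_commodity_only(self, tiny_nutrients):
        comp = pd.DataFrame(
            [("F_SUGAR", "SUGAR", 1.0)],
            columns=["food_id", "commodity_id", "fraction"],
        )
        recalls = pd.DataFrame(
            [("S", "F_SUGAR", 100.0)],
            columns=["subject_id", "food_id", "grams_consumed"],
        )
        out, _ = self._run(recalls, comp, tiny_nutrients, pd.Series({"S": 2000.0}))
        row = out.set_index("subject_id").loc["S"]
        assert row["natural_unbound_g"] == 0.0
        assert row["added_unbound_g"] == 0.0
        assert row["added_bound_g"] == pytest.approx(50.0)
        assert row["total_g"] == pytest.approx(50.0)

    def test_fruit_only_all_natural(
        self, tiny_composition, tiny_nutrients
    ):
        recalls = pd.DataFrame(
            [("S", "F_FRUIT", 120.0)],
            columns=["subject_id", "food_id", "grams_consumed"],
        )
        out, _ = self._run(
            recalls, tiny_composition, tiny_nutrients, pd.Series({"S": 1800.0})
        )
        row = out.set_index("subject_id").loc["S"]
        assert row["all_added_g"] == 0.0
        assert row["total_g"] == pytest.approx(row["natural_unbound_g"])

    def test_component_identities(self, small_scenario):
        _, t = small_scenario
        recalls = t["recalls"][t["recalls"]["reliable"]]
        energy = t["subjects"].set_index("subject_id")["energy_kcal"]
        out, _ = self._run(recalls, t["composition"], t["nutrients"], energy)
        assert np.allclose(
            out["all_added_g"], out["added_unbound_g"] + out["added_bound_g"], atol=1e-9
        )
        assert np.allclose(
            out["total_g"], out["all_added_g"] + out["natural_unbound_g"], atol=1e-9
        )
        assert (out[list(fr.intake.COMPONENT_COLUMNS)] >= 0).all().all()

    def test_zero_energy_flagged(self, tiny_composition, tiny_nutrients):
        recalls = pd.DataFrame(
            [("S", "F_FRUIT", 100.0)],
            columns=["subject_id", "food_id", "grams_consumed"],
        )
        out, _ = self._run(
            recalls, tiny_composition, tiny_nutrients, pd.Series({"S": 0.0})
        )
        row = out.set_index("subject_id").loc["S"]
        assert row["zero_energy"]
        assert np.isnan(row["total_pct_energy"])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        split=st.floats(min_value=0.05, max_value=0.95),
        grams=st.floats(min_value=1.0, max_value=500.0),
    )
    def test_splitting_records_invariant(
        self, split, grams, tiny_composition, tiny_nutrients
    ):
        """Splitting a recall into parts leaves every component unchanged."""
        whole = pd.DataFrame(
            [("S", "F_FRUIT", grams)],
            columns=["subject_id", "food_id", "grams_consumed"],
        )
        parts = pd.DataFrame(
            [("S", "F_FRUIT", grams * split), ("S", "F_FRUIT", grams * (1 - split))],
            columns=["subject_id", "food_id", "grams_consumed"],
        )
        energy = pd.Series({"S": 2000.0})
        a, _ = self._run(whole, tiny_composition, tiny_nutrients, energy)
        b, _ = self._run(parts, tiny_composition, tiny_nutrients, energy)
        for col in fr.intake.COMPONENT_COLUMNS:
            assert a[col].iloc[0] == pytest.approx(b[col].iloc[0], abs=1e-9)

    def test_monotone_in_grams(self, tiny_composition, tiny_nutrients):
        energy = pd.Series({"S": 2000.0})
        prev = None
        for grams in (50.0, 100.0, 200.0):
            recalls = pd.DataFrame(
                [("S", "F_DESSERT", grams), ("S", "F_SODA", 30.0)],
                columns=["subject_id", "food_id", "grams_consumed"],
            )
            out, _ = self._run(recalls, tiny_composition, tiny_nutrients, energy)
            row = out.set_index("subject_id").loc["S", list(fr.intake.COMPONENT_COLUMNS)]
            if prev is not None:
                assert (row.to_numpy() >= prev.to_numpy() - 1e-12).all()
            prev = row

    def test_mass_conservation_vs_commodity_sugar(self, small_scenario):
        """Total estimated fructose never exceeds the sugar mass consumed."""
        _, t = small_scenario
        recalls = t["recalls"][t["recalls"]["reliable"]]
        energy = t["subjects"].set_index("subject_id")["energy_kcal"]
        out, _ = self._run(recalls, t["composition"], t["nutrients"], energy)
        masses = fr.decompose(recalls, t["composition"])
        carb = t["nutrients"].set_index("commodity_id")["carb_per_100g"] / 100.0
        sugar_mass = (
            (masses["mass_g"] * masses["commodity_id"].map(carb))
            .groupby(masses["subject_id"])
            .sum()
        )
        got = out.set_index("subject_id")["total_g"]
        assert (got <= sugar_mass.loc[got.index] + 1e-9).all()

    def test_unresolved_contributes_zero_and_audited(self, tiny_composition):
        nut = pd.DataFrame(
            {
                "commodity_id": ["APPLE", "ORANGE", "OJ", "SUGAR", "CORN"],
                "fructose_per_100g": [6.0, np.nan, np.nan, 0.0, 0.0],
                "carb_per_100g": [14.0, 11.54, 10.0, 100.0, 100.0],
                "sucrose_per_100g": [0.0, 0.0, 0.0, 100.0, 0.0],
                "is_added_sugar": [False, False, False, True, True],
                "sweetener_class": ["none", "none", "none", "cane_beet",
                                    "corn_sweetener"],
                "family_id": [None, None, "ORANGE", None, None],
            }
        )
        audit = build_fraction_audit(nut)
        a = audit.set_index("commodity_id")
        assert a.loc["OJ", "provenance"] == "unresolved"
        assert a.loc["ORANGE", "provenance"] == "unresolved"
        assert a.loc["OJ", "fraction"] == 0.0


def test_imputation_neutrality():
    """Withholding fructose values leaves commodities with direct values
    untouched (same seed, different missing fraction)."""
    base = fr.ScenarioConfig(n_subjects=40, seed=4, missing_fructose_fraction=0.0)
    withheld = base.model_copy(update={"missing_fructose_fraction": 0.4})
    _, nut0 = fr.generate_food_db(base)
    _, nut1 = fr.generate_food_db(withheld)
    a0 = build_fraction_audit(nut0).set_index("commodity_id")
    a1 = build_fraction_audit(nut1).set_index("commodity_id")
    still_direct = a1[a1["provenance"] == "direct"].index
    pd.testing.assert_series_equal(
        a0.loc[still_direct, "fraction"], a1.loc[still_direct, "fraction"]
    )
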