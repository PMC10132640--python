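import math

import pytest

from paleoiso.foodweb import (
    FoodGroup,
    FoodItem,
    MacronutrientProfile,
    aggregate_group,
    bulk_from_fractions,
    energy_fraction_delta,
    load_food_groups,
    protein_delta_mass_balance,
    suess_correct,
    write_food_groups,
)


def item(**kw):
    base = dict(id="x", group_label="C3", era="modern", d13C_bulk=-20.0, d15N=3.0)
    base.update(kw)
    return FoodItem(**base)


class TestSuessCorrect:
    def test_modern_item_shifted_by_default(self):
        out = suess_correct(item(d13C_bulk=-20.0))
        assert out.d13C_bulk == pytest.approx(-18.5)
        assert out.suess_applied

    def test_archaeological_item_unchanged(self):
        arch = item(era="archaeological", d13C_bulk=-10.0)
        assert suess_correct(arch).d13C_bulk == pytest.approx(-10.0)

    def test_double_application_guarded(self):
        once = suess_correct(item())
        with pytest.raises(ValueError, match="already applied"):
            suess_correct(once)

    def test_missing_era_rejected_at_construction(self):
        with pytest.raises(ValueError):
            item(era=None)


class TestEnergyFractionDelta:
    @pytest.mark.parametrize(
        "fat_share,expected",
        [(0.0, -25.0), (1.0, -31.5), (12 / 13, -31.0)],
    )
    def test_linear_between_carb_and_fat_offsets(self, fat_share, expected):
        assert energy_fraction_delta(-25.5, fat_share) == pytest.approx(expected)

    @pytest.mark.parametrize("bad", [-0.1, 1.1])
    def test_fat_share_bounds(self, bad):
        with pytest.raises(ValueError):
            energy_fraction_delta(-25.5, bad)


class TestMassBalance:
    @pytest.mark.parametrize(
        "p,e,d_prot,d_en,bulk_expected",
        [(14, 86, -26.5, -25.3, -25.5), (76, 24, -12.7, -17.8, -13.9)],
    )
    def test_bulk_reconstruction_matches_printed_rows(
        self, p, e, d_prot, d_en, bulk_expected
    ):
        assert round(bulk_from_fractions(p, e, d_prot, d_en), 1) == bulk_expected

    def test_single_macronutrient_limit(self):
        # all calories from protein: protein delta equals bulk
        assert protein_delta_mass_balance(-20.0, 100, 0, -99.0) == pytest.approx(-20.0)

    def test_protein_and_bulk_are_inverses(self):
        d_prot = protein_delta_mass_balance(-19.8, 73, 27, -25.8)
        assert bulk_from_fractions(73, 27, d_prot, -25.8) == pytest.approx(-19.8)

    def test_zero_protein_rejected(self):
        with pytest.raises(ValueError):
            protein_delta_mass_balance(-20.0, 0, 100, -20.0)


class TestAggregateGroup:
    def prof(self, p=14.0):
        return MacronutrientProfile(protein_pct=p, energy_pct=100 - p)

    def test_single_item_has_zero_sd(self):
        g = aggregate_group(
            [item(era="archaeological", d13C_bulk=-25.5)], [self.prof()], "C3"
        )
        assert g.d13C_bulk == pytest.approx(-25.5, abs=1e-9)
        assert g.d13C_bulk_sd == 0.0
        assert g.n_items == 1

    def test_two_item_sample_and_population_sd(self):
        items = [
            item(id="a", era="archaeological", d13C_bulk=-24.0),
            item(id="b", era="archaeological", d13C_bulk=-26.0),
        ]
        profs = [self.prof(), self.prof()]
        g = aggregate_group(items, profs, "C3")
        assert g.d13C_bulk == pytest.approx(-25.0)
        assert g.d13C_bulk_sd == pytest.approx(math.sqrt(2.0))
        g0 = aggregate_group(items, profs, "C3", ddof=0)
        assert g0.d13C_bulk_sd == pytest.approx(1.0)

    def test_mean_invariant_to_item_order(self):
        items = [
            item(id=str(i), era="archaeological", d13C_bulk=v)
            for i, v in enumerate([-22.0, -26.0, -24.5])
        ]
        profs = [self.prof()] * 3
        a = aggregate_group(items, profs, "C3")
        b = aggregate_group(items[::-1], profs, "C3")
        assert a.d13C_bulk == pytest.approx(b.d13C_bulk)
        assert a.d15N_protein == pytest.approx(b.d15N_protein)

    def test_output_closes_mass_balance(self):
        items = [
            item(id="a", era="archaeological", d13C_bulk=-24.0),
            item(id="b", era="archaeological", d13C_bulk=-26.0),
        ]
        profs = [self.prof(10.0), self.prof(20.0)]
        g = aggregate_group(items, profs, "C3")
        assert abs(g.mass_balance_residual()) <= 0.05

    def test_uncorrected_modern_item_rejected(self):
        with pytest.raises(ValueError, match="Suess"):
            aggregate_group([item()], [self.prof()], "C3")

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="no items"):
            aggregate_group(
                [item(era="archaeological")], [self.prof()], "M1"
            )

    def test_five_group_matrix_from_fixture_items(self):
        labels = ["C3", "C4CAM", "FWTERR", "M1", "M2"]
        items = [
            item(id=l, group_label=l, era="archaeological", d13C_bulk=-20.0 - i)
            for i, l in enumerate(labels)
        ]
        profs = [self.prof()] * 5
        mat = [aggregate_group(items, profs, l) for l in labels]
        assert [g.name for g in mat] == labels
        for g in mat:
            assert abs(g.mass_balance_residual()) <= 0.05
            assert g.protein_pct + g.energy_pct == pytest.approx(100.0)


class TestPackagedSourceMatrix:
    def test_five_groups_with_expected_names(self, groups):
        assert [g.name for g in groups] == ["C3", "C4CAM", "FWTERR", "M1", "M2"]

    def test_mass_balance_closure_within_005_permil(self, groups):
        for g in groups:
            assert abs(g.mass_balance_residual()) <= 0.05, g.name

    def test_roundtrip_io(self, groups, tmp_path):
        p = tmp_path / "m.csv"
        write_food_groups(groups, p)
        back = load_food_groups(p)
        assert back == groups
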