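"""Record types, table I/O, aggregation and socioeconomic categorization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from upfsim.records import (
    FoodRecord,
    NovaGroup,
    NutrientTotals,
    RowError,
    SchemaError,
    aggregate_intake,
    derive_food_security,
    derive_pir_category,
    normalize_description,
    read_food_table,
    write_food_table,
)
from .conftest import random_classified_foods

FOOD_HEADER = "participant_id,food_code,description,energy_kcal,sodium_mg,added_sugar_g,fiber_g\n"


class TestFoodTableIO:
    def test_well_formed_rows_parse_identically(self, tmp_path):
        path = tmp_path / "foods.csv"
        path.write_text(
            FOOD_HEADER
            + "P1,11111111,\"Soft drink, cola\",150,50,40,0\n"
            + "P1,22222222,APPLE RAW,95,2,18.9,4.4\n"
            + "P2,33333333,MILK WHOLE PLAIN,149,105,0,0\n"
        )
        foods = read_food_table(path)
        assert len(foods) == 3
        assert foods[0].description == "SOFT DRINK COLA"  # normalized
        assert foods[1].added_sugar == 18.9
        assert all(f.nova_group is NovaGroup.UNCLASSIFIED for f in foods)

    def test_negative_nutrient_rejected_with_line_number(self, tmp_path):
        path = tmp_path / "foods.csv"
        path.write_text(FOOD_HEADER + "P1,11111111,X,100,-5,0,0\n")
        with pytest.raises(RowError) as err:
            read_food_table(path)
        assert err.value.rows == [2]

    def test_missing_added_sugar_is_row_error_not_zero(self, tmp_path):
        path = tmp_path / "foods.csv"
        path.write_text(FOOD_HEADER + "P1,11111111,X,100,50,,1\n")
        with pytest.raises(RowError):
            read_food_table(path)

    def test_header_only_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "foods.csv"
        path.write_text(FOOD_HEADER)
        assert read_food_table(path) == []

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "foods.csv"
        path.write_text("participant_id,food_code,description,energy_kcal\nP1,1,X,10\n")
        with pytest.raises(SchemaError):
            read_food_table(path)

    def test_round_trip_preserves_numeric_fields_exactly(self, tmp_path):
        rng = np.random.default_rng(3)
        foods = random_classified_foods(rng, n_participants=4)
        path = tmp_path / "out.csv"
        write_food_table(foods, path)
        back = read_food_table(path)
        assert len(back) == len(foods)
        for a, b in zip(foods, back):
            assert (a.energy, a.sodium, a.added_sugar, a.fiber) == (
                b.energy, b.sodium, b.added_sugar, b.fiber,
            )
            assert a.nova_group is b.nova_group


class TestAggregation:
    def test_two_item_sum_splits_upf_pool(self):
        foods = [
            FoodRecord("P1", 11111111, "UPF ITEM", 500, 800, 10, 1,
                       nova_group=NovaGroup.ULTRA_PROCESSED),
            FoodRecord("P1", 22222222, "PLAIN ITEM", 500, 200, 5, 4,
                       nova_group=NovaGroup.MINIMALLY_PROCESSED),
        ]
        (intake,) = aggregate_intake(foods)
        assert intake.total.energy == 1000 and intake.total.sodium == 1000
        assert intake.upf.energy == 500 and intake.upf.sodium == 800

    def test_no_upf_items_gives_zero_upf_pool(self):
        foods = [
            FoodRecord("P1", 1, "A", 100, 10, 1, 1, nova_group=NovaGroup.MINIMALLY_PROCESSED),
            FoodRecord("P1", 2, "B", 200, 20, 2, 2, nova_group=NovaGroup.PROCESSED),
        ]
        (intake,) = aggregate_intake(foods)
        assert intake.upf.energy == 0 and intake.upf.sodium == 0

    def test_unclassified_item_blocks_aggregation(self):
        foods = [FoodRecord("P1", 1, "MYSTERY", 100, 10, 1, 1)]
        with pytest.raises(ValueError, match="UNCLASSIFIED"):
            aggregate_intake(foods)

    def test_matches_brute_force_per_group_summation(self):
        rng = np.random.default_rng(11)
        foods = random_classified_foods(rng, n_participants=6, max_items=10)
        intakes = {i.participant_id: i for i in aggregate_intake(foods)}
        # independent oracle: explicit per-participant loop
        for pid in {f.participant_id for f in foods}:
            total = NutrientTotals()
            upf = NutrientTotals()
            for f in foods:
                if f.participant_id != pid:
                    continue
                item = NutrientTotals(f.energy, f.sodium, f.added_sugar, f.fiber)
                total = total + item
                if f.nova_group is NovaGroup.ULTRA_PROCESSED:
                    upf = upf + item
            got = intakes[pid]
            assert got.total.as_dict() == total.as_dict()
            assert got.upf.as_dict() == upf.as_dict()

    def test_zero_energy_participant_flagged_not_dropped(self):
        foods = [FoodRecord("P1", 1, "SALT", 0, 500, 0, 0,
                            nova_group=NovaGroup.CULINARY_INGREDIENT)]
        (intake,) = aggregate_intake(foods)
        assert intake.zero_energy


class TestSocioeconomicCategories:
    @pytest.mark.parametrize(
        "pir,expected",
        [(1.29, "low"), (1.30, "near_poverty"), (1.85, "near_poverty"), (1.86, "higher"), (0.0, "low")],
    )
    def test_pir_bands_with_inclusive_boundaries(self, pir, expected):
        assert derive_pir_category(pir) == expected

    def test_negative_pir_rejected(self):
        with pytest.raises(ValueError):
            derive_pir_category(-0.1)

    @pytest.mark.parametrize(
        "score,level,insecure",
        [(0, "high", False), (1, "marginal", False), (2, "marginal", False),
         (3, "low", True), (5, "low", True), (6, "very_low", True), (10, "very_low", True)],
    )
    def test_food_security_cutpoints_and_binary_indicator(self, score, level, insecure):
        assert derive_food_security(score) == (level, insecure)

    @pytest.mark.parametrize("score", [-1, 11])
    def test_out_of_range_score_rejected(self, score):
        with pytest.raises(ValueError):
            derive_food_security(score)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(min_value=0, max_value=10, allow_nan=False))
    def test_pir_category_monotone_in_pir(self, pir):
        order = {"low": 0, "near_poverty": 1, "higher": 2}
        a = order[derive_pir_category(pir)]
        b = order[derive_pir_category(pir + 0.01)]
        assert a <= b

    def test_food_security_level_monotone_in_score(self):
        order = {"high": 0, "marginal": 1, "low": 2, "very_low": 3}
        levels = [order[derive_food_security(s)[0]] for s in range(11)]
        assert levels == sorted(levels)


def test_normalization_collapses_punctuation_and_case():
    assert normalize_description("Soft drink,  cola (diet)!") == "SOFT DRINK COLA DIET"
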