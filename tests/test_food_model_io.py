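"""Domain types, table IO round-trips, and the EWCFG recommendation grid."""

import pandas as pd
import pytest

from hcst.food_model_io import (
    FoodGroup,
    NutrientProfilePerRA,
    Respondent,
    Sex,
    ThresholdSet,
    dri_group_label,
    read_food_table,
    read_recalls,
    read_respondents,
    recommended_servings,
    write_food_table,
    write_recalls,
    write_respondents,
    RECALL_COLUMNS,
)
from hcst.synthetic_data import CohortSpec, DietSpec, generate_cohort


class TestDomainTypes:
    def test_satfat_cannot_exceed_total_fat(self):
        with pytest.raises(ValueError, match="sat_fat_g"):
            NutrientProfilePerRA(total_fat_g=1.0, sat_fat_g=2.0, sugars_g=0, sodium_mg=0)

    def test_thresholds_must_be_ordered(self):
        with pytest.raises(ValueError):
            ThresholdSet(lower_fat_g=11, upper_fat_g=10)

    def test_default_thresholds_are_the_published_constants(self):
        t = ThresholdSet()
        assert (t.lower_fat_g, t.lower_sugars_g, t.lower_sodium_mg) == (3, 6, 140)
        assert (t.upper_fat_g, t.upper_sugars_g, t.upper_sodium_mg, t.upper_satfat_g) == (
            10, 19, 360, 2,
        )

    def test_respondent_missing_height_is_eer_ineligible(self):
        r = Respondent(respondent_id="r1", age_years=8, sex=Sex.F, weight_kg=30,
                       height_m=None, survey_weight=1.0)
        assert not r.eer_eligible

    def test_young_child_without_pal_is_still_eligible(self):
        r = Respondent(respondent_id="r2", age_years=4, sex=Sex.M, weight_kg=18,
                       height_m=1.05, pal=None, survey_weight=1.0)
        assert r.eer_eligible


class TestRoundTrips:
    def test_food_table_round_trip(self, tmp_path, foods, config):
        path = tmp_path / "foods.csv"
        write_food_table(foods, path)
        again = read_food_table(path, config.taxonomy)
        assert again == foods

    def test_respondent_and_recall_round_trip(self, tmp_path, config):
        respondents, items, _ = generate_cohort(
            CohortSpec(n_respondents=25, n_replicates=4), DietSpec(), 3, config
        )
        write_respondents(respondents, tmp_path / "r.csv")
        write_recalls(items, tmp_path / "i.csv")
        assert read_respondents(tmp_path / "r.csv") == respondents
        assert read_recalls(tmp_path / "i.csv") == items


class TestReaderErrors:
    def test_missing_column_names_the_column(self, tmp_path, config):
        p = tmp_path / "bad.csv"
        p.write_text("food_id,description\na,b\n")
        with pytest.raises(ValueError, match="food_group"):
            read_food_table(p, config.taxonomy)

    def test_invalid_profile_names_the_food(self, tmp_path, foods, config):
        write_food_table(foods, tmp_path / "f.csv")
        df = pd.read_csv(tmp_path / "f.csv")
        df.loc[0, "sat_fat_g_per_ra"] = df.loc[0, "total_fat_g_per_ra"] + 5
        df.to_csv(tmp_path / "f.csv", index=False)
        with pytest.raises(ValueError, match=df.loc[0, "food_id"]):
            read_food_table(tmp_path / "f.csv", config.taxonomy)

    def test_unknown_subgroup_is_rejected(self, tmp_path, foods, config):
        write_food_table(foods, tmp_path / "f.csv")
        df = pd.read_csv(tmp_path / "f.csv")
        df.loc[0, "subgroup"] = "astronaut_food"
        df.to_csv(tmp_path / "f.csv", index=False)
        with pytest.raises(ValueError, match="astronaut_food"):
            read_food_table(tmp_path / "f.csv", config.taxonomy)

    def test_empty_recall_file_with_header_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text(",".join(RECALL_COLUMNS) + "\n")
        assert read_recalls(p) == []

    def test_duplicate_respondent_id_is_an_error(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text(
            "respondent_id,age_years,sex,weight_kg,height_m,pal,survey_weight\n"
            "r1,5,M,20,1.1,,1\nr1,6,F,22,1.15,,1\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_respondents(p)

    def test_blank_anthropometry_parses_as_ineligible(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text(
            "respondent_id,age_years,sex,weight_kg,height_m,pal,survey_weight\n"
            "r1,10,F,32,,LOW_ACTIVE,1\n"
        )
        (r,) = read_respondents(p)
        assert r.height_m is None and not r.eer_eligible

    def test_tab_delimited_tables_are_sniffed(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text(
            "respondent_id\tage_years\tsex\tweight_kg\theight_m\tpal\tsurvey_weight\n"
            "r1\t10\tF\t32\t1.4\tLOW_ACTIVE\t1\n"
        )
        (r,) = read_respondents(p)
        assert r.age_years == 10 and r.sex is Sex.F


class TestRecommendedServings:
    @pytest.mark.parametrize(
        "age,sex,group,expected",
        [
            (15, Sex.M, FoodGroup.VEG_FRUIT, (8, 8)),
            (2.5, Sex.F, FoodGroup.MILK_ALT, (2, 2)),
            (10, Sex.F, FoodGroup.MEAT_ALT, (1, 2)),
            (6, Sex.M, FoodGroup.GRAIN, (4, 4)),
            (16, Sex.F, FoodGroup.VEG_FRUIT, (7, 7)),
            (14, Sex.M, FoodGroup.MEAT_ALT, (3, 3)),
        ],
    )
    def test_recommendation_grid(self, age, sex, group, expected):
        assert recommended_servings(age, sex)[group] == expected

    def test_age_out_of_range_is_an_error(self):
        with pytest.raises(ValueError):
            recommended_servings(19.0, Sex.M)
        with pytest.raises(ValueError):
            recommended_servings(1.9, Sex.F)

    def test_piecewise_constant_within_bands_and_positive_totals(self):
        for sex in Sex:
            prev = None
            for age10 in range(20, 190):
                age = age10 / 10.0
                label = dri_group_label(age, sex)
                servings = recommended_servings(age, sex)
                assert sum(lo for lo, _ in servings.values()) > 0
                if prev is not None and prev[0] == label:
                    assert servings == prev[1]
                prev = (label, servings)
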