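"""Contingents, frequency tables, residency summaries, sex-ratio tests."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

import sturseq as ss
from conftest import make_seq

# Published cross-population behavior counts (six study populations).
PUBLISHED_COUNTS = pd.DataFrame(
    {
        "HEC": [30, 80, 14, 33, 42, 17, 22],
        "GB": [17, 35, 74, 8, 30, 21, 0],
        "SLRE": [0, 5, 45, 44, 0, 0, 0],
        "BSR": [3, 3, 11, 1, 0, 0, 0],
        "ELS": [0, 24, 0, 0, 4, 0, 0],
        "ELE": [29, 22, 1, 0, 3, 0, 0],
    },
    index=[
        "annual_spring_river",
        "intermittent_spring_river",
        "intermittent_two_step",
        "river_resident",
        "annual_summer_river",
        "annual_winter_river",
        "annual_interlake",
    ],
)


class TestRouteSignature:
    def make_regional(self, labels, start=dt.date(2020, 1, 1)):
        return make_seq(labels, start=start, alphabet=tuple(sorted(set(labels))))

    def test_winter_lake_spring_river_roundtrip(self):
        year = ["LSC"] * 100 + ["DR"] * 30 + ["LSC"] * 236
        seq = self.make_regional(year * 3)
        assert ss.route_signature(seq, "annual_spring_river") == "LSC→DR"

    def test_resident_yields_single_region(self):
        seq = self.make_regional(["SLRE"] * 900)
        assert ss.route_signature(seq, "river_resident") == "SLRE"

    def test_interlake_three_region_route(self):
        year = ["LSC"] * 110 + ["DR"] * 15 + ["LE"] * 120 + ["DR"] * 15 + ["LSC"] * 106
        seq = self.make_regional(year * 3)
        assert ss.route_signature(seq, "annual_interlake") == "LSC→DR→LE"

    def test_all_missing_rejected(self):
        seq = make_seq([ss.MISSING] * 10, alphabet=("LM",))
        with pytest.raises(ValueError):
            ss.route_signature(seq, "river_resident")


class TestContingents:
    def frame(self, rows):
        return pd.DataFrame(
            rows, columns=["population", "fish_id", "behavior", "signature"]
        )

    def test_shared_behavior_and_route_is_one_contingent(self):
        table, totals = ss.tabulate_contingents(
            self.frame(
                [
                    ("HEC", "f1", "annual_spring_river", "LSC→DR"),
                    ("HEC", "f2", "annual_spring_river", "LSC→DR"),
                ]
            )
        )
        assert len(table) == 1 and table["count"].iloc[0] == 2
        assert totals["HEC"] == 1

    def test_different_spawning_rivers_are_distinct_contingents(self):
        table, totals = ss.tabulate_contingents(
            self.frame(
                [
                    ("HEC", "f1", "annual_spring_river", "LSC→DR"),
                    ("HEC", "f2", "annual_spring_river", "LSC→SCR"),
                ]
            )
        )
        assert len(table) == 2 and totals["HEC"] == 2

    def test_empty_input_gives_empty_table(self):
        table, totals = ss.tabulate_contingents(self.frame([]))
        assert table.empty and totals.empty

    def test_counts_invariant_to_fish_order(self):
        rows = [
            ("GB", "f1", "intermittent_two_step", "LM→MR"),
            ("GB", "f2", "river_resident", "MR"),
            ("GB", "f3", "intermittent_two_step", "LM→MR"),
        ]
        t1, _ = ss.tabulate_contingents(self.frame(rows))
        t2, _ = ss.tabulate_contingents(self.frame(rows[::-1]))
        pd.testing.assert_frame_equal(t1, t2)


class TestFrequencyTable:
    def test_reproduces_published_totals_and_percents(self):
        ft = ss.frequency_table_from_counts(PUBLISHED_COUNTS)
        assert ft.grand_total == 618
        assert ft.row_totals["intermittent_spring_river"] == 169
        assert ft.row_percents["intermittent_spring_river"] == 27
        assert list(ft.row_totals) == [79, 169, 145, 86, 79, 38, 22]
        assert list(ft.row_percents) == [13, 27, 23, 14, 13, 6, 4]
        assert list(ft.column_totals) == [238, 185, 94, 18, 28, 55]

    def test_population_percent_shares(self):
        ft = ss.frequency_table_from_counts(PUBLISHED_COUNTS)
        assert ft.percents.loc["intermittent_spring_river", "ELS"] == 86
        assert ft.percents.loc["annual_spring_river", "ELE"] == 53
        assert ft.percents.loc["intermittent_two_step", "BSR"] == 61
        assert ft.percents.loc["annual_interlake", "HEC"] == 9

    def test_single_fish_cohort_is_hundred_percent(self):
        assignments = pd.DataFrame(
            {"population": ["P"], "behavior": ["river_resident"]}
        )
        ft = ss.behavior_frequency_table(assignments)
        assert ft.percents.loc["river_resident", "P"] == 100

    def test_unclassified_excluded_from_totals(self):
        assignments = pd.DataFrame(
            {
                "population": ["P", "P", "P"],
                "behavior": ["river_resident", ss.UNCLASSIFIED, "river_resident"],
            }
        )
        ft = ss.behavior_frequency_table(assignments)
        assert ft.grand_total == 2


class TestResidencySummary:
    def test_degenerate_group_mean_only(self):
        df = pd.DataFrame(
            {
                "population": ["P"] * 3 + ["Q"],
                "behavior": ["river_resident"] * 3 + ["annual_spring_river"],
                "lake_residency": [1.0, 1.0, 1.0, 0.9],
            }
        )
        out = ss.lake_residency_summary(df).set_index(["population", "behavior"])
        row = out.loc[("P", "river_resident")]
        assert row["mean_pct_lake"] == 100.0 and row["sd_pct_lake"] == 0.0
        assert pd.isna(out.loc[("Q", "annual_spring_river")]["sd_pct_lake"])

    def test_sample_sd_of_two_fish(self):
        df = pd.DataFrame(
            {
                "population": ["P", "P"],
                "behavior": ["annual_summer_river"] * 2,
                "lake_residency": [0.4, 0.6],
            }
        )
        out = ss.lake_residency_summary(df)
        assert out["mean_pct_lake"].iloc[0] == pytest.approx(50.0)
        assert round(out["sd_pct_lake"].iloc[0]) == 14  # sample SD, rounded

    def test_empty_group_absent(self):
        out = ss.lake_residency_summary(
            pd.DataFrame(columns=["population", "behavior", "lake_residency"])
        )
        assert out.empty


class TestSexRatio:
    def test_zero_chi_square_at_expectation(self):
        chi2, df, p = ss.sex_ratio_test(20, 20, 1.0)
        assert chi2 == 0.0 and df == 1 and p == pytest.approx(1.0)

    def test_thirty_ten_under_even_ratio(self):
        chi2, _, p = ss.sex_ratio_test(30, 10, 1.0)
        assert chi2 == pytest.approx(10.0)
        assert p == pytest.approx(0.001565, abs=1e-5)

    def test_balanced_counts_under_skewed_population(self):
        chi2, _, _ = ss.sex_ratio_test(20, 20, 1.05)
        assert chi2 == pytest.approx(0.0238, abs=1e-4)

    def test_matches_textbook_formula_on_random_inputs(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            m, f = int(rng.integers(5, 80)), int(rng.integers(5, 80))
            r = float(rng.uniform(0.3, 3.0))
            chi2, _, _ = ss.sex_ratio_test(m, f, r)
            n = m + f
            em, ef = n * r / (1 + r), n / (1 + r)
            assert chi2 == pytest.approx((m - em) ** 2 / em + (f - ef) ** 2 / ef)
            assert chi2 >= 0.0

    def test_small_expected_count_warns(self):
        with pytest.warns(UserWarning, match="below 5"):
            ss.sex_ratio_test(4, 2, 1.0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            ss.sex_ratio_test(0, 0, 1.0)
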