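"""Rule cascade: episodes, periodicity, residency, archetype recovery."""

import datetime as dt

import numpy as np
import pytest

import sturseq as ss
from conftest import make_seq

D0 = dt.date(2020, 1, 1)


def habitat_regional(hab_labels, region_by_habitat=None):
    region_by_habitat = region_by_habitat or {"lake": "LM", "river": "MR"}
    reg_labels = [
        region_by_habitat.get(s, s) if s not in (ss.MISSING, ss.VOID) else s
        for s in hab_labels
    ]
    hab = make_seq(hab_labels, alphabet=("river", "lake"))
    reg = make_seq(reg_labels, alphabet=tuple(sorted(set(region_by_habitat.values()))))
    return hab, reg


class TestRiverEpisodes:
    def test_may_run_overlaps_spawning_window(self):
        labels = ["lake"] * 120 + ["river"] * 20 + ["lake"] * 100
        hab, reg = habitat_regional(labels)
        eps = ss.extract_river_episodes(hab, reg)
        assert len(eps) == 1
        ep = eps[0]
        assert ep.region == "MR" and ep.duration_days == 20
        assert ep.overlaps_spawning_window
        assert ep.entry == D0 + dt.timedelta(days=120)

    def test_all_lake_sequence_has_no_episodes(self):
        hab, reg = habitat_regional(["lake"] * 30)
        assert ss.extract_river_episodes(hab, reg) == []

    def test_lake_day_splits_episodes(self):
        hab, reg = habitat_regional(["river"] * 3 + ["lake"] + ["river"] * 2)
        eps = ss.extract_river_episodes(hab, reg)
        assert [e.duration_days for e in eps] == [3, 2]

    def test_misaligned_sequences_rejected(self):
        hab, _ = habitat_regional(["lake"] * 5)
        _, reg = habitat_regional(["lake"] * 6)
        with pytest.raises(ValueError):
            ss.extract_river_episodes(hab, reg)


class TestPeriodicityRatio:
    @pytest.mark.parametrize(
        "years,trips,ratio,cls",
        [
            (6, 6, 1.0, "annual"),
            (6, 3, 2.0, "intermittent"),
            (3, 2, 1.5, "annual"),  # boundary inclusive
            (6, 4, 1.5, "annual"),
            (9.06, 6, 1.51, "intermittent"),
        ],
    )
    def test_ratio_and_class(self, years, trips, ratio, cls):
        r, c = ss.periodicity_ratio(years, trips)
        assert r == pytest.approx(ratio) and c == cls

    def test_enumerated_grid_matches_quotient_rule(self):
        for years in range(2, 11):
            for trips in range(1, years + 1):
                r, c = ss.periodicity_ratio(float(years), trips)
                assert r == years / trips
                assert c == ("annual" if r <= 1.5 else "intermittent")

    def test_zero_trips_rejected(self):
        with pytest.raises(ValueError):
            ss.periodicity_ratio(6.0, 0)


class TestLakeResidency:
    def test_all_lake_is_one(self):
        assert ss.lake_residency(make_seq(["lake"] * 10)) == 1.0

    def test_half_lake_year(self):
        seq = make_seq(["lake"] * 183 + ["river"] * 183)
        assert ss.lake_residency(seq) == 0.5

    def test_missing_and_void_excluded(self):
        seq = make_seq([ss.MISSING, "lake", "river", ss.VOID], alphabet=("lake", "river"))
        assert ss.lake_residency(seq) == 0.5

    def test_lake_st_clair_counts_as_lake(self):
        seq = make_seq(["lake_st_clair", "river"])
        assert ss.lake_residency(seq) == 0.5

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            ss.lake_residency(make_seq([ss.MISSING] * 3, alphabet=("lake",)))

    def test_spring_migrant_residency_matches_day_counts(self, small_sequences):
        hab, _ = small_sequences
        seq = hab["annual_spring_river_00"]
        observed = seq.states[seq.observed_mask()]
        expected = sum(1 for s in observed if s != "river") / len(observed)
        assert ss.lake_residency(seq) == pytest.approx(expected)


class TestClassifyArchetypes:
    def test_noise_free_archetypes_recovered(self, small_cohort, small_sequences):
        _, _, _, truth = small_cohort
        hab, reg = small_sequences
        expected = truth.set_index("fish_id")["behavior"]
        for fid in hab:
            a = ss.classify_behavior(hab[fid], reg[fid])
            assert a.behavior == expected[fid], fid

    def test_fifty_fifty_two_step_variant(self, stations, stations_df):
        from sturseq.synthetic import two_step_fifty_fifty

        cfg = ss.SimulationConfig(years=6, seed=13)
        det, _ = ss.simulate_individual(two_step_fifty_fifty(), cfg, "f1", stations)
        frame = (cfg.start_date, cfg.end_date)
        hab = ss.build_daily_sequence(det, stations_df, frame, "habitat")
        reg = ss.build_daily_sequence(det, stations_df, frame, "region")
        a = ss.classify_behavior(hab, reg)
        assert a.behavior == "intermittent_two_step"
        assert a.residency_class == "fifty_fifty"

    def test_river_resident_lake_fraction_below_threshold(self, small_sequences):
        hab, reg = small_sequences
        a = ss.classify_behavior(hab["river_resident_00"], reg["river_resident_00"])
        assert a.behavior == "river_resident"
        assert a.lake_residency <= ss.RuleConfig().resident_max_lake_fraction

    def test_periodicity_only_reported_for_spring_migrants(self, small_sequences):
        hab, reg = small_sequences
        for fid in hab:
            a = ss.classify_behavior(hab[fid], reg[fid])
            if a.behavior.endswith("spring_river"):
                assert a.periodicity_ratio is not None
            else:
                assert a.periodicity_ratio is None

    def test_nonconforming_sequence_unclassified(self):
        # a mid-winter river excursion missing every seasonal window
        year = ["lake"] * 31 + ["river"] * 48 + ["lake"] * 286
        hab, reg = habitat_regional(year * 2)
        a = ss.classify_behavior(hab, reg)
        assert a.behavior == ss.UNCLASSIFIED

    def test_determinism(self, small_sequences):
        hab, reg = small_sequences
        fid = "annual_winter_river_01"
        a1 = ss.classify_behavior(hab[fid], reg[fid])
        a2 = ss.classify_behavior(hab[fid], reg[fid])
        assert a1 == a2


class TestClassifyCohort:
    def test_two_archetype_cohort_yields_two_pure_clusters(
        self, small_sequences, stations_df
    ):
        hab, reg = small_sequences
        keep = [f for f in hab if f.startswith(("river_resident", "annual_spring"))]
        seqs = {f: (hab[f], reg[f]) for f in keep}
        cost = ss.build_cost_matrix(
            hab[keep[0]].alphabet, [("river", "lake"), ("river", "lake_st_clair")]
        )
        mat = ss.dissimilarity_matrix({f: hab[f] for f in keep}, cost)
        assignments, report = ss.classify_cohort(seqs, mat)
        sel = report["cluster_guide"]["selection"]
        assert sel["chosen_k"] == 2
        by_cluster = {}
        for a in assignments:
            by_cluster.setdefault(a.cluster_id, set()).add(a.behavior)
        assert all(len(v) == 1 for v in by_cluster.values())
        assert report["cluster_guide"]["disagreement_rate"] == 0.0

    def test_rules_label_even_when_clustering_degenerates(self, small_sequences):
        hab, reg = small_sequences
        keep = [f for f in hab if f.startswith("river_resident")]
        seqs = {f: (hab[f], reg[f]) for f in keep}
        # n = 2 < 3: selection errors are reported, rules still label
        mat = ss.DissimilarityMatrix(tuple(keep), np.zeros((2, 2)))
        assignments, report = ss.classify_cohort(seqs, mat)
        assert "error" in report["cluster_guide"]
        assert all(a.behavior == "river_resident" for a in assignments)

    def test_seven_archetype_cohort_shows_seven_labels(self, small_sequences):
        hab, reg = small_sequences
        seqs = {f: (hab[f], reg[f]) for f in hab}
        assignments, _ = ss.classify_cohort(seqs, None)
        assert {a.behavior for a in assignments} == set(ss.BEHAVIORS)
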