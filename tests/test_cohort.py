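import itertools

import numpy as np
import pandas as pd
import pytest

from cghcnv.cohort import (
    build_call_matrix,
    classify_frequency,
    compare_family_counts,
    flag_outliers,
    map_report,
    percent,
    share_sets,
)
from cghcnv.model import ArrayExperiment, CallMatrix, GeneCall, GeneticMap


def cnv_call(array_id, gene_id, is_cnv=True, is_pav=False, direction="gain",
             median_m=0.6):
    if not is_cnv:
        direction, median_m = "none", 0.1
    return GeneCall(array_id, gene_id, 12, 11 if is_cnv else 2, direction,
                    median_m if not is_pav else 3.5, is_cnv=is_cnv,
                    is_pav=is_pav)


def experiments_for(family_id, individuals):
    return [
        ArrayExperiment(f"arr_{ind}", ind, "P1", {"p": (1, 0, 1, 0)},
                        family_id=family_id)
        for ind in individuals
    ]


def matrix_from_sets(family_id, sets_by_individual):
    genes = sorted(set().union(*sets_by_individual.values()))
    df = pd.DataFrame(
        {ind: [g in s for g in genes]
         for ind, s in sets_by_individual.items()},
        index=pd.Index(genes, name="gene_id"),
    )
    return CallMatrix(family_id, df)


class TestBuildCallMatrix:
    def test_carrier_counts(self):
        exps = experiments_for("F1", ["i1", "i2"])
        calls = [cnv_call("arr_i1", "gA"), cnv_call("arr_i1", "gB"),
                 cnv_call("arr_i2", "gB")]
        m = build_call_matrix(calls, exps)
        assert m.carrier_counts["gA"] == 1
        assert m.carrier_counts["gB"] == 2
        assert m.individual_counts.tolist() == [2, 1]

    def test_empty_calls_empty_matrix(self):
        m = build_call_matrix([], experiments_for("F1", ["i1"]))
        assert m.calls.shape == (0, 1)

    def test_non_cnv_calls_do_not_populate(self):
        exps = experiments_for("F1", ["i1"])
        m = build_call_matrix([cnv_call("arr_i1", "gA", is_cnv=False)], exps)
        assert m.calls.shape[0] == 0

    def test_mixed_families_rejected(self):
        exps = experiments_for("F1", ["i1"]) + experiments_for("F2", ["i2"])
        calls = [cnv_call("arr_i1", "gA"), cnv_call("arr_i2", "gA")]
        with pytest.raises(ValueError, match="families"):
            build_call_matrix(calls, exps)

    def test_individuals_without_calls_get_zero_columns(self):
        exps = experiments_for("F1", ["i1", "i2", "i3"])
        m = build_call_matrix([cnv_call("arr_i1", "gA")], exps)
        assert list(m.individuals) == ["i1", "i2", "i3"]
        assert m.individual_counts.tolist() == [1, 0, 0]


class TestClassifyFrequency:
    def test_infrequent_fraction(self):
        m = matrix_from_sets("F1", {
            "i1": {"g1", "g2", "g3"}, "i2": {"g2"}, "i3": {"g2"},
        })
        classes, summary = classify_frequency(m)
        assert classes["g1"] == "infrequent"
        assert classes["g2"] == "common"
        assert summary["pct_infrequent"] == pytest.approx(100 * 2 / 3)
        assert summary["pct_common"] + summary["pct_infrequent"] == pytest.approx(100)

    def test_all_common(self):
        m = matrix_from_sets("F1", {"i1": {"g1"}, "i2": {"g1"}})
        _, summary = classify_frequency(m)
        assert summary["pct_infrequent"] == 0.0

    def test_printed_family_percentages_average_to_64(self):
        # means of the four per-family infrequent percentages
        assert round(np.mean([63.2, 65.5, 70.3, 58.6])) == 64

    def test_pav_percentage(self):
        m = matrix_from_sets("F1", {"i1": {"g1", "g2"}})
        calls = [cnv_call("arr_i1", "g1", is_pav=True), cnv_call("arr_i1", "g2")]
        _, summary = classify_frequency(m, calls)
        assert summary["pct_pav"] == pytest.approx(50.0)


class TestShareSets:
    def test_core_and_pairwise(self):
        matrices = {
            "F1": matrix_from_sets("F1", {"i": {"A", "B", "C"}}),
            "F2": matrix_from_sets("F2", {"i": {"B", "C"}}),
            "F3": matrix_from_sets("F3", {"i": {"C"}}),
        }
        res = share_sets(matrices)
        assert res["core"] == {"C"}
        assert res["pairwise"][("F1", "F2")] == 2
        assert res["pairwise"][("F1", "F3")] == 1
        assert res["pairwise"][("F2", "F3")] == 1
        assert res["n_union"] == 3

    def test_disjoint_families_empty_core(self):
        matrices = {
            "F1": matrix_from_sets("F1", {"i": {"A"}}),
            "F2": matrix_from_sets("F2", {"i": {"B"}}),
        }
        assert share_sets(matrices)["core"] == set()

    def test_union_matches_inclusion_exclusion_oracle(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(40)]
        sets = {
            f"F{k}": set(rng.choice(genes, size=rng.integers(5, 30),
                                    replace=False))
            for k in range(3)
        }
        matrices = {f: matrix_from_sets(f, {"i": s}) for f, s in sets.items()}
        res = share_sets(matrices)
        s1, s2, s3 = (sets[f"F{k}"] for k in range(3))
        incl_excl = (
            len(s1) + len(s2) + len(s3)
            - len(s1 & s2) - len(s1 & s3) - len(s2 & s3)
            + len(s1 & s2 & s3)
        )
        assert res["n_union"] == incl_excl == len(s1 | s2 | s3)

    def test_symmetry_and_bound(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(30)]
        sets = {f: set(rng.choice(genes, size=10, replace=False))
                for f in ("F1", "F2")}
        res = share_sets({f: matrix_from_sets(f, {"i": s})
                          for f, s in sets.items()})
        shared = res["pairwise"][("F1", "F2")]
        assert shared == len(sets["F1"] & sets["F2"])
        assert shared <= min(len(sets["F1"]), len(sets["F2"]))

    def test_single_family_rejected(self):
        with pytest.raises(ValueError):
            share_sets({"F1": matrix_from_sets("F1", {"i": {"A"}})})


class TestCompareFamilyCounts:
    def test_shifted_group_detected(self):
        rng = np.random.default_rng(8)
        counts = {f: rng.normal(100, 10, size=19) for f in ("A", "B", "C")}
        counts["D"] = rng.normal(150, 10, size=19)  # 5 SD shift
        res = compare_family_counts(counts)
        tukey = res["tukey"]
        involving_d = tukey[(tukey["family_a"] == "D") | (tukey["family_b"] == "D")]
        others = tukey[(tukey["family_a"] != "D") & (tukey["family_b"] != "D")]
        assert involving_d["reject"].all()
        assert (involving_d["p_adj"] < 1e-7).all()
        assert not others["reject"].any()

    def test_identical_constant_groups_f_zero(self):
        res = compare_family_counts({"A": [5, 5, 5], "B": [5, 5, 5]})
        assert res["F"] == 0.0
        assert res["p_value"] == 1.0
        assert not res["tukey"]["reject"].any()

    def test_type_one_error_rate(self):
        # familywise rejection rate of Tukey HSD at alpha 0.05 under the null
        rng = np.random.default_rng(9)
        n_reps, rejections = 120, 0
        for _ in range(n_reps):
            counts = {f: rng.normal(100, 10, size=19) for f in "ABCD"}
            res = compare_family_counts(counts)
            rejections += bool(res["tukey"]["reject"].any())
        assert rejections / n_reps <= 0.12

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_family_counts({"A": [1, 2, 3]})


class TestFlagOutliers:
    def test_extreme_individual_flagged(self):
        sets = {f"i{k}": {"gA"} for k in range(10)}
        sets["big"] = {f"g{j}" for j in range(40)}
        m = matrix_from_sets("F1", sets)
        assert flag_outliers(m) == ["big"]

    def test_homogeneous_family_unflagged(self):
        m = matrix_from_sets("F1", {"i1": {"gA"}, "i2": {"gA"}, "i3": {"gA"}})
        assert flag_outliers(m) == []


def simple_map(entries):
    genes, lgs, pos = zip(*entries)
    return GeneticMap(pd.DataFrame(
        {"linkage_group": lgs, "position": list(map(float, pos))},
        index=pd.Index(genes, name="gene_id"),
    ))


class TestMapReport:
    def test_adjacent_distances(self):
        gmap = simple_map([("g1", "LG1", 10), ("g2", "LG1", 20),
                           ("g3", "LG1", 40), ("x1", "LG1", 0),
                           ("x2", "LG1", 100)])
        matrices = {"F1": matrix_from_sets("F1", {"i": {"g1", "g2", "g3"}})}
        res = map_report(matrices, gmap)
        assert res["mean_adjacent_cm"]["F1"] == pytest.approx(15.0)
        assert res["per_lg_counts"]["LG1"] == 3

    def test_one_cm_cluster(self):
        gmap = simple_map([("g1", "LG1", 12.3), ("g2", "LG1", 12.9),
                           ("g3", "LG1", 30.0), ("x1", "LG1", 0),
                           ("x2", "LG1", 60)])
        matrices = {"F1": matrix_from_sets("F1", {"i": {"g1", "g2", "g3"}})}
        res = map_report(matrices, gmap)
        assert res["n_clusters"] == 1
        assert set(res["clusters"][0]["genes"]) == {"g1", "g2"}

    def test_unmapped_genes_counted(self):
        gmap = simple_map([("g1", "LG1", 5), ("g2", "LG1", 25),
                           ("x1", "LG1", 0)])
        matrices = {"F1": matrix_from_sets(
            "F1", {"i": {"g1", "g2", "ghost"}})}
        res = map_report(matrices, gmap)
        assert res["n_mapped"] == 2
        assert res["n_unmapped"] == 1

    def test_invariant_to_lg_labels(self):
        entries = [("g1", "LG1", 10), ("g2", "LG1", 20), ("g3", "LG2", 5),
                   ("g4", "LG2", 9), ("x1", "LG1", 0), ("x2", "LG2", 0)]
        relabeled = [(g, {"LG1": "LGB", "LG2": "LGA"}[lg], p)
                     for g, lg, p in entries]
        matrices = {"F1": matrix_from_sets(
            "F1", {"i": {"g1", "g2", "g3", "g4"}})}
        r1 = map_report(matrices, simple_map(entries))
        r2 = map_report(matrices, simple_map(relabeled))
        assert r1["mean_adjacent_cm"] == r2["mean_adjacent_cm"]
        assert sorted(r1["per_lg_counts"].tolist()) == sorted(
            r2["per_lg_counts"].tolist())

    def test_ks_null_p_values_roughly_uniform(self):
        # CNV positions drawn from the same distribution as the map
        rng = np.random.default_rng(10)
        n_reps, hits = 400, 0
        for _ in range(n_reps):
            a = rng.uniform(0, 1, size=60)
            b = rng.uniform(0, 1, size=200)
            from scipy import stats
            if stats.ks_2samp(a, b).pvalue < 0.05:
                hits += 1
        assert abs(hits / n_reps - 0.05) < 0.03


class TestPercent:
    def test_mapped_cnv_fraction(self):
        assert percent(210, 3612) == 5.8

    def test_surveyed_mapped_fraction(self):
        assert percent(1284, 14078, ndigits=None) == 9
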