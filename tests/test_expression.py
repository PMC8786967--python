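import math

import numpy as np
import pandas as pd
import pytest

import _oracles
from teregkit import expression as expr
from teregkit.io import te_copy_ids
from teregkit.simulate import simulate_nb_counts


def make_design(na=2, nb=2):
    cols = [f"a{i+1}" for i in range(na)] + [f"b{i+1}" for i in range(nb)]
    return cols, expr.GroupDesign.from_suffix(cols, "a", "b")


class TestNormalization:
    def test_rpkm_unit_case(self):
        counts = pd.DataFrame({"s": [10, 0]}, index=["f1", "f2"])
        lengths = pd.Series([1_000, 500], index=["f1", "f2"])
        out = expr.rpkm(counts, lengths, pd.Series({"s": 1_000_000}))
        assert out.loc["f1", "s"] == 10.0
        assert out.loc["f2", "s"] == 0.0

    def test_rpkm_halves_when_libsize_doubles(self):
        counts = pd.DataFrame({"s": [10]}, index=["f"])
        lengths = pd.Series([1_000], index=["f"])
        one = expr.rpkm(counts, lengths, pd.Series({"s": 1e6}))
        two = expr.rpkm(counts, lengths, pd.Series({"s": 2e6}))
        assert two.loc["f", "s"] == one.loc["f", "s"] / 2

    def test_rpkm_zero_libsize_rejected(self):
        counts = pd.DataFrame({"s": [0]}, index=["f"])
        with pytest.raises(ValueError, match="library size"):
            expr.rpkm(counts, pd.Series([100], index=["f"]), pd.Series({"s": 0}))

    def test_rpm_unit_case(self):
        counts = pd.DataFrame({"s": [5, 0]}, index=["f1", "f2"])
        out = expr.rpm(counts, pd.Series({"s": 1_000_000}))
        assert out.loc["f1", "s"] == 5.0 and out.loc["f2", "s"] == 0.0


class TestFilterExpressed:
    @pytest.mark.parametrize(
        "mean_a,mean_b,kept",
        [(0.5, 1.2, True), (0.5, 0.9, False), (1.0, 1.0, False)],  # strict >
    )
    def test_group_mean_threshold(self, mean_a, mean_b, kept):
        cols, design = make_design()
        row = pd.DataFrame([[mean_a, mean_a, mean_b, mean_b]], columns=cols, index=["f"])
        result = expr.filter_expressed(row, design, threshold=1.0)
        assert ("f" in result) == kept


class TestSizeFactors:
    def test_hand_computed_two_sample_case(self):
        # counts [[10,20],[100,200]]: ratios to geomean give medians (1/sqrt2, sqrt2)
        counts = pd.DataFrame([[10, 20], [100, 200]], columns=["s1", "s2"])
        sf = expr.size_factors(counts)
        assert sf["s1"] == pytest.approx(1 / math.sqrt(2))
        assert sf["s2"] == pytest.approx(math.sqrt(2))

    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame([[5, 5], [9, 9]], columns=["s1", "s2"])
        assert np.allclose(expr.size_factors(counts), 1.0)

    def test_single_sample_factor_is_one(self):
        counts = pd.DataFrame({"s1": [3, 7]})
        assert expr.size_factors(counts)["s1"] == pytest.approx(1.0)

    def test_fallback_to_library_size(self, caplog):
        counts = pd.DataFrame([[0, 4], [6, 0]], columns=["s1", "s2"])
        sf = expr.size_factors(counts)
        assert np.isclose(np.exp(np.mean(np.log(sf))), 1.0)

    def test_recovers_planted_library_factors_within_5pct(self):
        counts, truth = simulate_nb_counts(3_000, seed=77)
        sf = expr.size_factors(counts)
        planted = pd.Series(truth["library_factors"])
        planted = planted / np.exp(np.mean(np.log(planted)))
        assert np.allclose(sf, planted, rtol=0.05)


class TestBH:
    def test_agrees_with_bruteforce_stepup(self):
        rng = np.random.default_rng(5)
        for n in (1, 2, 10, 100):
            p = rng.uniform(size=n)
            assert np.allclose(expr.bh_fdr(p), _oracles.bh_stepup(list(p)))

    def test_monotone_nondecreasing_in_p(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=50)
        fdr = expr.bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(fdr[order]) >= -1e-12).all()


class TestNBDifferential:
    def test_identical_groups_are_null(self):
        cols, design = make_design(3, 3)
        base = np.array([[100, 100, 100], [30, 30, 30], [250, 250, 250]])
        counts = pd.DataFrame(np.hstack([base, base]), columns=cols)
        table = expr.nb_differential(counts, design)
        assert np.allclose(table["log2fc"], 0)
        assert (table["p"] > 0.99).all()

    def test_label_swap_negates_log2fc_and_keeps_p(self):
        counts, _ = simulate_nb_counts(200, seed=3)
        cols = list(counts.columns)
        fwd = expr.nb_differential(counts, expr.GroupDesign.from_suffix(cols, "a", "b"))
        rev = expr.nb_differential(counts, expr.GroupDesign.from_suffix(cols, "b", "a"))
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        assert np.allclose(fwd["p"], rev["p"])

    def test_planted_eightfold_feature_detected(self):
        # planted true 8-fold change, dispersion 0.05, n = 3 vs 3
        counts, truth = simulate_nb_counts(
            500, planted=np.arange(10), planted_fc=8.0, dispersion=0.05, seed=21
        )
        design = expr.GroupDesign.from_suffix(list(counts.columns), "a", "b")
        table = expr.nb_differential(counts, design)
        calls = expr.call_differential(table, 4.0, 0.05)
        assert (calls.iloc[:10] == "up").mean() >= 0.9

    def test_zero_count_features_dropped(self):
        cols, design = make_design(2, 2)
        counts = pd.DataFrame([[0, 0, 0, 0], [5, 6, 7, 8]], columns=cols, index=["z", "k"])
        table = expr.nb_differential(counts, design)
        assert list(table.index) == ["k"]

    def test_empty_group_rejected(self):
        counts = pd.DataFrame({"a1": [1], "a2": [2]})
        with pytest.raises(ValueError):
            expr.GroupDesign.from_suffix(list(counts.columns), "a", "b")


class TestCallDifferential:
    @pytest.mark.parametrize(
        "log2fc,fdr,fold,expected",
        [
            (2.1, 0.01, 4.0, "up"),
            (2.1, 0.06, 4.0, "ns"),
            (-0.6, 0.001, 1.5, "down"),  # |log2fc| >= log2(1.5) ~ 0.585
            (1.9, 0.01, 4.0, "ns"),
        ],
    )
    def test_threshold_application(self, log2fc, fdr, fold, expected):
        table = pd.DataFrame({"log2fc": [log2fc], "fdr": [fdr]})
        assert expr.call_differential(table, fold, 0.05).iloc[0] == expected


class TestDirectionProportions:
    def test_percentages(self):
        out = expr.direction_proportions(264, 44)
        assert out["down_pct"] == pytest.approx(85.7, abs=0.05)
        assert out["up_pct"] == pytest.approx(14.3, abs=0.05)


class TestSubfamilyRanking:
    def _te_table(self, spec):
        rows = []
        pos = 0
        for subfam, n in spec.items():
            for _ in range(n):
                rows.append(("chr1", pos, pos + 100, "+", subfam, "F", "LTR"))
                pos += 200
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "strand", "subfamily", "family", "class"]
        )

    def test_filters_and_proportion(self):
        te = self._te_table({"big": 100, "small": 50, "quiet": 200})
        ids = te_copy_ids(te)
        calls = pd.Series("ns", index=ids)
        calls[ids[te["subfamily"] == "big"][:20]] = "up"     # 100 copies, 20 DETE
        calls[ids[te["subfamily"] == "small"][:20]] = "up"   # 50 copies -> excluded
        calls[ids[te["subfamily"] == "quiet"][:7]] = "up"    # 7 DETE -> excluded
        out = expr.rank_subfamily_dete_proportion(calls, te)
        assert list(out.index) == ["big"]
        assert out.loc["big", "up_proportion"] == pytest.approx(0.20)

    def test_planted_subfamily_ranks_first(self):
        te = self._te_table({"planted": 90, "null1": 300, "null2": 150})
        ids = te_copy_ids(te)
        calls = pd.Series("ns", index=ids)
        calls[ids[te["subfamily"] == "planted"]] = "up"      # all copies differential
        calls[ids[te["subfamily"] == "null1"][:30]] = "up"   # 10% differential
        out = expr.rank_subfamily_dete_proportion(calls, te)
        assert out.index[0] == "planted" and out["up_rank"].iloc[0] == 1


class TestTopVariance:
    def test_selects_highest_variance_rows(self):
        m = pd.DataFrame(
            {"s1": [1.0, 0.0, 5.0], "s2": [1.0, 5.0, 6.0], "s3": [1.0, 10.0, 7.0]},
            index=["flat", "steep", "mild"],
        )
        z = expr.top_variance_subfamilies(m, k=2)
        assert set(z.index) == {"steep", "mild"}
        assert np.allclose(z.mean(axis=1), 0)
        assert np.allclose(z.std(axis=1, ddof=1), 1)

    def test_constant_row_gets_zero_zscores(self):
        m = pd.DataFrame({"s1": [1.0], "s2": [1.0], "s3": [1.0]}, index=["flat"])
        z = expr.top_variance_subfamilies(m, k=1)
        assert (z.loc["flat"] == 0).all()

    def test_k_larger_than_available_keeps_all(self):
        m = pd.DataFrame({"s1": [1.0, 2.0], "s2": [2.0, 1.0]}, index=["x", "y"])
        assert len(expr.top_variance_subfamilies(m, k=10)) == 2


class TestAggregateSubfamily:
    def test_additivity_and_mass_conservation(self, toy):
        ids = te_copy_ids(toy.te_table)
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(0, 50, size=(len(ids), 2)), index=ids, columns=["s1", "s2"]
        )
        agg = expr.aggregate_subfamily(counts, toy.te_table)
        assert (agg.sum(axis=0) == counts.sum(axis=0)).all()
        sub = toy.te_table["subfamily"].iloc[0]
        members = ids[(toy.te_table["subfamily"] == sub).to_numpy()]
        assert agg.loc[sub, "s1"] == counts.loc[members, "s1"].sum()

    def test_unknown_copy_rejected_by_name(self, toy):
        counts = pd.DataFrame({"s1": [1]}, index=["chrX:0-1(+)ghost"])
        with pytest.raises(ValueError, match="ghost"):
            expr.aggregate_subfamily(counts, toy.te_table)


class TestClassifySoloLTR:
    def _frame(self, rows):
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "strand", "subfamily", "family", "class"]
        )

    def test_gap_plus_one_convention_at_41bp(self):
        # LTR [1000,1960) vs internal [2000,8000): distance 2000-1960+1 = 41
        ltr = self._frame([("chr1", 1000, 1960, "+", "L", "F", "LTR")])
        internal = self._frame([("chr1", 2000, 8000, "+", "I", "F", "LTR")])
        assert expr.classify_solo_ltr(ltr, internal, 100).iloc[0] == "proviral"
        assert expr.classify_solo_ltr(ltr, internal, 40).iloc[0] == "solo"

    def test_no_internal_on_chromosome_is_solo(self):
        ltr = self._frame([("chr1", 1000, 1960, "+", "L", "F", "LTR")])
        internal = self._frame([("chr2", 2000, 8000, "+", "I", "F", "LTR")])
        assert expr.classify_solo_ltr(ltr, internal, 100).iloc[0] == "solo"

    def test_matches_planted_truth_on_toy_genome(self, toy):
        labels = expr.classify_solo_ltr(
            toy.te_table[toy.te_table["subfamily"] == "LTR5x"],
            toy.te_table[toy.te_table["subfamily"] == "ERVKx-int"],
            100,
        )
        proviral = set(toy.truth.proviral_ltr_ids["LTR5x"])
        solo = set(toy.truth.solo_ltr_ids["LTR5x"])
        for copy_id, label in labels.items():
            assert label == ("proviral" if copy_id in proviral else "solo")
            assert (copy_id in proviral) or (copy_id in solo)
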