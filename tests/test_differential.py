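import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import oracles
from mtfe import (
    anova_oneway,
    anova_tukey,
    bh_adjust,
    paired_ttest,
    set_overlap,
    significant_sets,
    two_sample_ttest,
)
from mtfe.differential import adjust_pvalues, fourgroup_comparisons, P_FLOOR
from mtfe.io_core import InputError


def _frame(rows, samples=None):
    rows = np.atleast_2d(np.asarray(rows, float))
    samples = samples or [f"S{j}" for j in range(rows.shape[1])]
    return pd.DataFrame(rows, index=[f"P{i}" for i in range(rows.shape[0])], columns=samples)


def _groups(sizes):
    labels = {}
    j = 0
    for g, n in sizes.items():
        for _ in range(n):
            labels[f"S{j}"] = g
            j += 1
    return labels


class TestAnova:
    def test_identical_constant_groups(self):
        frame = _frame([[5.0] * 8])
        res = anova_oneway(frame, _groups({"a": 2, "b": 2, "c": 2, "d": 2}))
        assert res["f"].iloc[0] == 0.0
        assert res["p"].iloc[0] == 1.0

    def test_matches_sums_of_squares_oracle(self):
        groups = [[1, 2, 3], [2, 3, 4], [3, 4, 5], [10, 11, 12]]
        frame = _frame([np.concatenate(groups)])
        res = anova_oneway(frame, _groups({"a": 3, "b": 3, "c": 3, "d": 3}))
        f_expected, p_expected = oracles.anova_f_oracle(groups)
        assert res["f"].iloc[0] == pytest.approx(f_expected, abs=1e-10)
        assert res["p"].iloc[0] == pytest.approx(p_expected, rel=1e-10)

    def test_random_instances_match_oracle_and_scipy(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            k = rng.integers(2, 5)
            sizes = rng.integers(2, 7, size=k)
            groups = [list(rng.normal(size=n)) for n in sizes]
            frame = _frame([np.concatenate(groups)])
            labels = _groups({f"g{i}": len(g) for i, g in enumerate(groups)})
            res = anova_oneway(frame, labels)
            f_o, p_o = oracles.anova_f_oracle(groups)
            f_s, p_s = stats.f_oneway(*groups)
            assert res["f"].iloc[0] == pytest.approx(f_o, rel=1e-8)
            assert res["p"].iloc[0] == pytest.approx(p_o, rel=1e-8)
            assert res["f"].iloc[0] == pytest.approx(f_s, rel=1e-8)

    def test_shift_and_scale_invariance_of_f(self):
        rng = np.random.default_rng(9)
        row = rng.normal(size=12)
        labels = _groups({"a": 4, "b": 4, "c": 4})
        f0 = anova_oneway(_frame([row]), labels)["f"].iloc[0]
        f_shift = anova_oneway(_frame([row + 13.7]), labels)["f"].iloc[0]
        f_scale = anova_oneway(_frame([row * 3.1]), labels)["f"].iloc[0]
        assert f_shift == pytest.approx(f0, rel=1e-10)
        assert f_scale == pytest.approx(f0, rel=1e-10)

    def test_missing_values_reduce_group_counts(self):
        row = np.array([1.0, np.nan, 2.0, 3.0, 4.0, 5.0])
        res = anova_oneway(_frame([row]), _groups({"a": 3, "b": 3}))
        assert res["n_a"].iloc[0] == 2

    def test_underpowered_protein_skipped(self):
        row = np.array([1.0, np.nan, np.nan, 2.0, 3.0, 4.0])
        table = anova_tukey(_frame([row]), _groups({"a": 3, "b": 3}))
        assert table.skipped == ["P0"]

    def test_group_entirely_missing_is_error(self):
        frame = _frame([[1.0, 2.0, np.nan, np.nan]])
        with pytest.raises(InputError, match="'b'"):
            anova_tukey(frame, _groups({"a": 2, "b": 2}))

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.5, 2.0])
    def test_alpha_bounds(self, alpha):
        with pytest.raises(InputError):
            anova_tukey(_frame([[1.0, 2.0, 3.0, 4.0]]), _groups({"a": 2, "b": 2}), alpha=alpha)


class TestTukey:
    def test_matches_scipy_tukey_hsd(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            k = int(rng.integers(3, 5))
            sizes = rng.integers(3, 8, size=k)
            groups = [rng.normal(size=n) for n in sizes]
            frame = _frame([np.concatenate(groups)])
            labels = _groups({f"g{i}": len(g) for i, g in enumerate(groups)})
            table = anova_tukey(frame, labels)
            ref = stats.tukey_hsd(*groups)
            for i in range(k):
                for j in range(i + 1, k):
                    col = f"tukey_p_g{i}_vs_g{j}"
                    assert table.table[col].iloc[0] == pytest.approx(
                        ref.pvalue[i, j], abs=1e-8
                    ), (i, j)

    def test_matches_hand_oracle(self):
        groups = [[1.0, 2.0, 3.0], [2.5, 3.5, 4.5, 5.0], [7.0, 8.0]]
        frame = _frame([np.concatenate(groups)])
        labels = _groups({"a": 3, "b": 4, "c": 2})
        table = anova_tukey(frame, labels)
        for (i, a), (j, b) in [((0, "a"), (1, "b")), ((0, "a"), (2, "c")), ((1, "b"), (2, "c"))]:
            expected = oracles.tukey_p_oracle(groups, i, j)
            assert table.table[f"tukey_p_{a}_vs_{b}"].iloc[0] == pytest.approx(expected, rel=1e-8)

    def test_monotone_in_mean_difference(self):
        # equal n, fixed within-group spread: larger |diff| -> smaller Tukey p
        pvals = []
        for delta in [0.5, 1.0, 2.0, 4.0]:
            groups = [[0.0, 1.0, 2.0], [delta, delta + 1.0, delta + 2.0],
                      [0.1, 1.1, 2.1], [0.2, 1.2, 2.2]]
            frame = _frame([np.concatenate(groups)])
            labels = _groups({"a": 3, "b": 3, "c": 3, "d": 3})
            table = anova_tukey(frame, labels)
            pvals.append(table.table["tukey_p_a_vs_b"].iloc[0])
        assert all(x >= y for x, y in zip(pvals, pvals[1:]))

    def test_fourgroup_comparison_names(self):
        comps = fourgroup_comparisons(("Ctrl", "DEN"), ("WT", "KO"))
        names = [c[2] for c in comps]
        assert names == [
            "KO_vs_WT.within_Ctrl",
            "KO_vs_WT.within_DEN",
            "DEN_vs_Ctrl.within_WT",
            "DEN_vs_Ctrl.within_KO",
        ]


class TestBhAdjust:
    def test_worked_example(self):
        # p*m/rank then cumulative min: all collapse to 0.04
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_matches_oracle_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(6)
        for _ in range(100):
            p = rng.random(size=rng.integers(1, 40))
            ours = bh_adjust(p)
            oracle = oracles.bh_oracle(list(p))
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(ours, oracle, rtol=1e-10)
            np.testing.assert_allclose(ours, ref, rtol=1e-10)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_bounds_property(self, p):
        out = bh_adjust(p)
        assert np.all(out >= np.asarray(p) - 1e-12)
        assert np.all(out <= 1.0 + 1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(InputError):
            bh_adjust([0.5, 1.2])

    def test_nan_passthrough(self):
        out = bh_adjust([0.02, np.nan, 0.5])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], [0.04, 0.5])

    def test_other_methods_against_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(13)
        p = rng.random(25)
        np.testing.assert_allclose(
            adjust_pvalues(p, "bonferroni"), multipletests(p, method="bonferroni")[1]
        )
        np.testing.assert_allclose(
            adjust_pvalues(p, "holm"), multipletests(p, method="holm")[1]
        )


class TestSignificantSets:
    def _table(self, sig_by_comp, universe):
        import mtfe.differential as d

        frame = pd.DataFrame(index=sorted(universe))
        frame["p"] = 0.5
        frame["p_adj"] = 0.5
        comps = []
        for comp, sig in sig_by_comp.items():
            frame[f"sig_{comp}"] = frame.index.isin(sig)
            comps.append(comp)
        return d.DifferentialTable(frame, groups=[], comparisons=comps, alpha=0.05)

    def test_disjoint_union(self):
        t = self._table({"c1": {"A", "B", "C"}, "c2": {"D", "E", "F", "G"}},
                        set("ABCDEFGH"))
        sets = significant_sets({"x": t})
        assert len(sets.union["x"]) == 7

    def test_nested_union(self):
        t = self._table({"c1": {"A", "B"}, "c2": {"A", "B", "C"}}, set("ABCD"))
        assert significant_sets({"x": t}).union["x"] == ["A", "B", "C"]

    def test_intersection_of_universes(self):
        t1 = self._table({"c": {"A", "B"}}, {"A", "B", "C"})
        t2 = self._table({"c": {"B", "Z"}}, {"B", "C", "Z"})
        sets = significant_sets({"x": t1, "y": t2})
        assert sets.union["x"] == ["B"]
        assert sets.union["y"] == ["B"]  # Z outside the shared universe

    def test_overlap_regions(self):
        regions = set_overlap({"X": ["A", "B"], "Y": ["B", "C"]})
        assert regions[frozenset({"X"})] == 1
        assert regions[frozenset({"X", "Y"})] == 1
        assert regions[frozenset({"Y"})] == 1

    def test_three_identical_sets(self):
        s = [f"p{i}" for i in range(5)]
        regions = set_overlap({"a": s, "b": s, "c": s})
        assert regions == {frozenset({"a", "b", "c"}): 5}

    def test_region_counts_sum_to_union(self):
        rng = np.random.default_rng(3)
        universe = [f"p{i}" for i in range(50)]
        sets = {
            name: [p for p in universe if rng.random() < 0.4]
            for name in ("a", "b", "c")
        }
        regions = set_overlap(sets)
        assert sum(regions.values()) == len(set().union(*map(set, sets.values())))


class TestPairedTtest:
    def _pairs(self, n):
        return {f"pr{i}": (f"T{i}", f"C{i}") for i in range(n)}

    def _frame(self, case_vals, ctrl_vals):
        case_vals = np.atleast_2d(case_vals)
        ctrl_vals = np.atleast_2d(ctrl_vals)
        n = case_vals.shape[1]
        cols = [f"T{i}" for i in range(n)] + [f"C{i}" for i in range(n)]
        return pd.DataFrame(
            np.hstack([case_vals, ctrl_vals]).astype(float),
            index=[f"P{i}" for i in range(case_vals.shape[0])],
            columns=cols,
        )

    def test_symmetric_differences_give_t0_p1(self):
        frame = self._frame([[1.0, -1.0]], [[0.0, 0.0]])
        res = paired_ttest(frame, self._pairs(2))
        assert res.table["t"].iloc[0] == 0.0
        assert res.table["p"].iloc[0] == pytest.approx(1.0)

    def test_hand_formula(self):
        # differences {1, 2, 3}: t = 2 / (1/sqrt(3))
        frame = self._frame([[1.0, 2.0, 3.0]], [[0.0, 0.0, 0.0]])
        res = paired_ttest(frame, self._pairs(3))
        t_o, p_o = oracles.paired_t_oracle([1.0, 2.0, 3.0])
        assert res.table["t"].iloc[0] == pytest.approx(2 / (1 / np.sqrt(3)), abs=1e-10)
        assert res.table["t"].iloc[0] == pytest.approx(t_o, rel=1e-10)
        assert res.table["p"].iloc[0] == pytest.approx(p_o, rel=1e-10)

    def test_matches_scipy_on_random_instances(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            n = int(rng.integers(3, 10))
            case, ctrl = rng.normal(size=n), rng.normal(size=n)
            res = paired_ttest(self._frame([case], [ctrl]), self._pairs(n))
            t_ref, p_ref = stats.ttest_rel(case, ctrl)
            assert res.table["t"].iloc[0] == pytest.approx(t_ref, rel=1e-8)
            assert res.table["p"].iloc[0] == pytest.approx(p_ref, rel=1e-8)

    def test_sign_matches_mean_difference(self):
        frame = self._frame([[0.0, 0.1, -0.2]], [[1.0, 1.1, 0.8]])
        res = paired_ttest(frame, self._pairs(3))
        assert np.sign(res.table["t"].iloc[0]) == np.sign(res.table["mean_diff"].iloc[0])

    def test_degenerate_zero_variance_flagged(self):
        frame = self._frame([[2.0, 2.0, 2.0]], [[1.0, 1.0, 1.0]])
        res = paired_ttest(frame, self._pairs(3))
        assert res.table["degenerate"].iloc[0]
        assert res.table["p"].iloc[0] == P_FLOOR

    def test_incomplete_pairs_dropped(self):
        frame = self._frame([[1.0, np.nan, 3.0]], [[0.0, 0.0, 0.0]])
        res = paired_ttest(frame, self._pairs(3))
        assert res.table["n_pairs"].iloc[0] == 2


class TestTwoSampleTtest:
    def test_identical_groups(self):
        frame = _frame([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]])
        res = two_sample_ttest(frame, _groups({"a": 3, "b": 3}))
        assert res["t"].iloc[0] == 0.0
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_hand_formula(self):
        frame = _frame([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
        res = two_sample_ttest(frame, _groups({"a": 3, "b": 3}))
        t_o, p_o = oracles.pooled_t_oracle([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res["t"].iloc[0] == pytest.approx(t_o, abs=1e-10)
        assert res["p"].iloc[0] == pytest.approx(p_o, rel=1e-10)

    def test_matches_scipy_equal_var(self):
        rng = np.random.default_rng(14)
        for _ in range(100):
            na, nb = int(rng.integers(2, 9)), int(rng.integers(2, 9))
            a, b = rng.normal(size=na), rng.normal(size=nb)
            frame = _frame([np.concatenate([a, b])])
            res = two_sample_ttest(frame, _groups({"a": na, "b": nb}), labels=("a", "b"))
            t_ref, p_ref = stats.ttest_ind(a, b, equal_var=True)
            assert res["t"].iloc[0] == pytest.approx(t_ref, rel=1e-8)
            assert res["p"].iloc[0] == pytest.approx(p_ref, rel=1e-8)

    def test_equal_variance_equals_welch_at_balanced_equal_var(self):
        # with equal n and equal sample variances, pooled t == Welch t
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = a + 2.5
        frame = _frame([np.concatenate([a, b])])
        res = two_sample_ttest(frame, _groups({"a": 4, "b": 4}), labels=("a", "b"))
        t_welch, _ = stats.ttest_ind(a, b, equal_var=False)
        assert res["t"].iloc[0] == pytest.approx(t_welch, rel=1e-12)

    def test_small_group_skipped(self):
        frame = _frame([[1.0, np.nan, 3.0, 4.0]])
        res = two_sample_ttest(frame, _groups({"a": 2, "b": 2}), labels=("a", "b"))
        assert np.isnan(res["t"].iloc[0])


class TestTypeIErrorControl:
    def test_null_configuration_fpr_within_binomial_bounds(self):
        """Global-null matrix: raw-p FPR inside the exact binomial 99% CI."""
        rng = np.random.default_rng(100)
        n_prot, alpha = 4000, 0.05
        X = rng.normal(size=(n_prot, 28))
        frame = pd.DataFrame(X, index=[f"P{i}" for i in range(n_prot)],
                             columns=[f"S{j}" for j in range(28)])
        labels = _groups({"a": 8, "b": 6, "c": 8, "d": 6})
        res = anova_oneway(frame, labels)
        fpr = float((res["p"] < alpha).mean())
        lo = stats.binom.ppf(0.005, n_prot, alpha) / n_prot
        hi = stats.binom.ppf(0.995, n_prot, alpha) / n_prot
        assert lo <= fpr <= hi
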