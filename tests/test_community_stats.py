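"""Group-comparison statistics against long-hand textbook oracles."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom, norm
from scipy.stats import t as t_dist
from scipy.stats import chi2 as chi2_dist

from endotraits import (
    fisher_exact_2x2,
    fligner_killeen,
    holm_adjust,
    richness_per_leaf,
    rowwise_fisher,
    t_test,
)


def welch_oracle(a, b):
    """Welch t-test from the textbook formulas, term by term."""
    na, nb = len(a), len(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    t = (np.mean(a) - np.mean(b)) / math.sqrt(va / na + vb / nb)
    df = (va / na + vb / nb) ** 2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    )
    p = 2 * t_dist.sf(abs(t), df)
    return t, df, p


def pooled_oracle(a, b):
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (
        na + nb - 2
    )
    t = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    return t, df, 2 * t_dist.sf(abs(t), df)


def fligner_oracle(groups):
    """Normal-scores statistic computed step by step from its definition."""
    centered = np.concatenate(
        [np.abs(np.asarray(g) - np.median(g)) for g in groups]
    )
    sizes = [len(g) for g in groups]
    ranks = pd.Series(centered).rank().to_numpy()  # midranks for ties
    N = len(centered)
    a = norm.ppf(0.5 + ranks / (2.0 * (N + 1)))
    abar = a.mean()
    s2 = ((a - abar) ** 2).sum() / (N - 1)
    stat = 0.0
    start = 0
    for n_g in sizes:
        stat += n_g * (a[start:start + n_g].mean() - abar) ** 2 / s2
        start += n_g
    return stat, chi2_dist.sf(stat, len(groups) - 1)


def fisher_oracle(table):
    """Two-sided p by enumerating all tables with the observed margins."""
    (a, b), (c, d) = table
    n = a + b + c + d
    r1, c1 = a + b, a + c
    pmf_obs = hypergeom.pmf(a, n, c1, r1)
    p = 0.0
    for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        pk = hypergeom.pmf(k, n, c1, r1)
        if pk <= pmf_obs * (1 + 1e-9):
            p += pk
    return min(p, 1.0)


class TestTTest:
    def test_identical_samples(self):
        r = t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == pytest.approx(0.0)
        assert r.pvalue == pytest.approx(1.0)

    def test_gross_separation(self):
        r = t_test([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert r.pvalue < 0.01

    @pytest.mark.parametrize("variant,oracle",
                             [("welch", welch_oracle), ("pooled", pooled_oracle)])
    def test_matches_formula_oracle(self, variant, oracle):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, size=14)
        b = rng.normal(0.5, 2, size=9)
        r = t_test(a, b, variant=variant)
        t, df, p = oracle(a, b)
        assert r.statistic == pytest.approx(t, abs=1e-10)
        assert r.df == pytest.approx(df, abs=1e-8)
        assert r.pvalue == pytest.approx(p, abs=1e-10)

    def test_validation(self):
        with pytest.raises(ValueError, match="zero variance"):
            t_test([1.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="at least 2"):
            t_test([1.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="variant"):
            t_test([1.0, 2.0], [3.0, 4.0], variant="bogus")


class TestFligner:
    def test_identical_groups(self):
        chi2, df, p = fligner_killeen({"a": [1, 2, 3, 4], "b": [1, 2, 3, 4]})
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1 and p == pytest.approx(1.0)

    def test_tenfold_sd_ratio_detected(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 50)
        b = rng.normal(0, 10, 50)
        _, _, p = fligner_killeen([a, b])
        assert p < 0.001

    def test_matches_score_formula_oracle(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(0, s, n) for s, n in ((1, 12), (3, 8), (2, 15))]
        chi2, df, p = fligner_killeen(groups)
        stat_o, p_o = fligner_oracle(groups)
        assert chi2 == pytest.approx(stat_o, abs=1e-8)
        assert p == pytest.approx(p_o, abs=1e-10)
        assert df == 2

    def test_location_shift_invariance(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 20), rng.normal(0, 2, 20)
        c1 = fligner_killeen([a, b])
        c2 = fligner_killeen([a + 100.0, b])
        # structural invariance, limited only by |x - median| rounding
        assert c1[0] == pytest.approx(c2[0], rel=1e-4)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            fligner_killeen([[2.0, 2.0], [2.0, 2.0]])
        with pytest.raises(ValueError, match="2 groups"):
            fligner_killeen([[1.0, 2.0]])


class TestFisher:
    def test_matches_enumeration_oracle(self):
        table = [[3, 1], [1, 3]]
        _, p = fisher_exact_2x2(table)
        assert p == pytest.approx(fisher_oracle(table), abs=1e-12)

    def test_balanced_table(self):
        _, p = fisher_exact_2x2([[5, 5], [5, 5]])
        assert p == pytest.approx(1.0)

    def test_extreme_table_smallest_attainable_p(self):
        table = [[0, 10], [10, 0]]
        _, p = fisher_exact_2x2(table)
        assert p == pytest.approx(fisher_oracle(table), abs=1e-12)
        assert p < 1e-4

    def test_transpose_and_double_swap_invariance(self):
        t = np.array([[7, 2], [3, 9]])
        _, p = fisher_exact_2x2(t)
        _, p_t = fisher_exact_2x2(t.T)
        _, p_sw = fisher_exact_2x2(t[::-1, ::-1])
        assert p == pytest.approx(p_t, abs=1e-12)
        assert p == pytest.approx(p_sw, abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact_2x2([[0, 0], [3, 4]])


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_adjust([0.04])[0] == pytest.approx(0.04)

    def test_stepwise_hand_example(self):
        adj = holm_adjust([0.01, 0.03, 0.04])
        assert np.allclose(adj, [0.03, 0.06, 0.06])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=12))
    def test_dominates_raw_and_capped_at_one(self, pvals):
        adj = holm_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(pvals)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestRowwiseFisher:
    def test_small_rows_flagged_na(self):
        table = pd.DataFrame(
            {"slow": [3, 20, 30], "fast": [2, 25, 10]},
            index=["tiny", "big1", "big2"],
        )
        out = rowwise_fisher(table)
        assert not out.loc["tiny", "tested"]
        assert np.isnan(out.loc["tiny", "p"])
        assert out.loc[["big1", "big2"], "tested"].all()
        # Holm spans only the tested rows
        tested_p = out.loc[["big1", "big2"], "p"]
        assert np.allclose(out.loc[["big1", "big2"], "p_adj"],
                           holm_adjust(tested_p))

    def test_extreme_association(self):
        table = pd.DataFrame(
            {"slow": [40, 0], "fast": [0, 40]}, index=["x", "y"])
        out = rowwise_fisher(table)
        assert (out["p_adj"] < 0.001).all()

    def test_row_p_is_row_vs_rest_collapse(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame(
            rng.integers(6, 30, size=(4, 2)), columns=["slow", "fast"],
            index=list("abcd"),
        )
        out = rowwise_fisher(table)
        for taxon in table.index:
            rest = table.drop(index=taxon).sum()
            _, p = fisher_exact_2x2(
                [[table.loc[taxon, "slow"], table.loc[taxon, "fast"]],
                 [rest["slow"], rest["fast"]]])
            assert out.loc[taxon, "p"] == pytest.approx(p, abs=1e-12)

    def test_needs_two_rows(self):
        with pytest.raises(ValueError):
            rowwise_fisher(pd.DataFrame({"slow": [3], "fast": [9]}))


class TestRichness:
    def test_distinct_otus_counted(self):
        meta = pd.DataFrame({
            "leaf_id": ["L1"] * 3,
            "method": ["sectioning"] * 3,
            "otu_id": ["o1", "o2", "o1"],
        })
        cells, summary, _ = richness_per_leaf(meta)
        assert cells.loc[0, "n_otus"] == 2

    def test_empty_cells_count_zero(self):
        meta = pd.DataFrame({
            "leaf_id": ["L1", "L1", "L2"],
            "method": ["sectioning", "maceration", "sectioning"],
            "otu_id": ["o1", "o2", "o3"],
        })
        cells, _, tests = richness_per_leaf(meta)
        l2mac = cells[(cells.leaf_id == "L2") & (cells.method == "maceration")]
        assert l2mac["n_otus"].iloc[0] == 0
        assert set(tests) == {"welch", "pooled"}

    def test_missing_column_named(self):
        with pytest.raises(ValueError, match="otu_id"):
            richness_per_leaf(pd.DataFrame({"leaf_id": [], "method": []}))

    def test_matches_generator_truth(self, small_community):
        cells, _, _ = richness_per_leaf(small_community.metadata)
        truth = small_community.truth["richness_per_leaf_method"]
        for _, row in cells.iterrows():
            key = f"{row.leaf_id}|{row.method}"
            assert row.n_otus == truth.get(key, 0)
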