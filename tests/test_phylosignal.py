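"""Blomberg's K, the random-tips permutation null, and BM simulation."""
import itertools
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from endotraits import (
    Phylogeny,
    blomberg_k,
    bm_simulate,
    bm_simulate_batch,
    rt_test,
    signal_scan,
    simulate_tree,
    summarize_scan,
)
from endotraits.phylosignal import SignalEngine

from conftest import oracle_blomberg_k, oracle_vcv


def star_tree(n, t=1.0):
    nwk = "(" + ",".join(f"s{i}:{t}" for i in range(n)) + ");"
    return Phylogeny.from_newick(nwk, is_path=False)


class TestBlombergK:
    def test_star_phylogeny_is_exactly_one(self):
        tree = star_tree(12, t=1.7)
        rng = np.random.default_rng(0)
        for _ in range(20):
            trait = pd.Series(rng.normal(size=12), index=tree.tips)
            assert blomberg_k(tree, trait) == pytest.approx(1.0, abs=1e-12)

    def test_two_tip_equal_branches_is_one(self):
        tree = Phylogeny.from_newick("(A:1,B:1);", is_path=False)
        trait = pd.Series({"A": 0.3, "B": 1.9})
        assert blomberg_k(tree, trait) == pytest.approx(1.0, abs=1e-12)

    def test_five_tip_matches_dense_gls_oracle(self, five_tip_newick):
        tree = Phylogeny.from_newick(five_tip_newick, is_path=False)
        resolved = tree.resolve_polytomies(seed=0)
        trait = pd.Series([1.0, 2.0, 5.0, 6.0, 9.0], index=list("ABCDE"))
        labels, C = oracle_vcv(five_tip_newick)
        expected = oracle_blomberg_k(C, trait[labels].to_numpy())
        assert blomberg_k(resolved, trait) == pytest.approx(expected, abs=1e-10)

    def test_constant_trait_rejected(self):
        tree = simulate_tree(6, seed=0)
        with pytest.raises(ValueError, match="constant"):
            blomberg_k(tree, pd.Series(1.0, index=tree.tips))

    @pytest.mark.parametrize("a,b", [(3.0, 2.0), (0.0, -1.5)])
    def test_invariant_to_affine_trait_transform(self, a, b):
        tree = simulate_tree(20, seed=3)
        trait = bm_simulate(tree, seed=5)
        assert blomberg_k(tree, a + b * trait) == pytest.approx(
            blomberg_k(tree, trait), abs=1e-8)

    def test_invariant_to_branch_rescaling(self):
        tree = simulate_tree(15, seed=4)
        trait = bm_simulate(tree, seed=6)
        k1 = blomberg_k(tree, trait)
        scaled = Phylogeny.from_newick(tree.as_newick(), is_path=False)
        for edge in scaled._tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= 7.3
        assert blomberg_k(scaled, trait) == pytest.approx(k1, abs=1e-8)

    def test_matches_r_picante(self, tmp_path):
        """Independent reference implementation (picante::Kcalc)."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not on PATH")
        tree = simulate_tree(12, seed=9)
        trait = bm_simulate(tree, seed=10) + 0.05 * np.arange(12)
        tree.write_newick(str(tmp_path / "t.nwk"))
        pd.DataFrame({"x": trait}).to_csv(tmp_path / "x.csv")
        script = (
            'suppressMessages({library(ape); library(picante)});'
            f'tr <- read.tree("{tmp_path}/t.nwk");'
            f'd <- read.csv("{tmp_path}/x.csv", row.names=1);'
            'cat(sprintf("%.10f", Kcalc(setNames(d$x, rownames(d))[tr$tip.label], tr)))'
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=300, check=True)
        assert blomberg_k(tree, trait) == pytest.approx(
            float(out.stdout.strip()), abs=1e-6)


class TestRandomTips:
    def test_exhaustive_matches_full_enumeration(self):
        nwk = "((A:1,B:1):1,(C:1,D:1):1);"
        tree = Phylogeny.from_newick(nwk, is_path=False)
        trait = pd.Series([0.1, 0.3, 1.2, 1.4], index=list("ABCD"))
        k_obs, p = rt_test(tree, trait, exhaustive=True)
        labels, C = oracle_vcv(nwk)
        x = trait[labels].to_numpy()
        ks = [oracle_blomberg_k(C, x[list(perm)])
              for perm in itertools.permutations(range(4))]
        n_exceed = sum(k >= k_obs - 1e-9 for k in ks)
        assert p * 24 == pytest.approx(n_exceed, abs=1e-9)
        assert k_obs == pytest.approx(oracle_blomberg_k(C, x), abs=1e-10)

    def test_p_floor_and_determinism(self):
        tree = simulate_tree(10, seed=1)
        trait = bm_simulate(tree, seed=2)
        k1, p1 = rt_test(tree, trait, n_perm=99, seed=42)
        k2, p2 = rt_test(tree, trait, n_perm=99, seed=42)
        assert (k1, p1) == (k2, p2)
        assert p1 >= 1 / 100

    def test_power_on_clade_structured_trait(self):
        # two deep clades, trait = clade indicator + small noise
        half = "(" + ",".join(f"{{side}}{i}:1" for i in range(8)) + "):10"
        nwk = f"({half.format(side='a')},{half.format(side='b')});"
        tree = Phylogeny.from_newick(nwk, is_path=False)
        indicator = pd.Series(
            [0.0] * 8 + [1.0] * 8,
            index=[f"a{i}" for i in range(8)] + [f"b{i}" for i in range(8)],
        )
        engine = SignalEngine(tree)
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(100):
            x = engine.align(indicator + 0.1 * pd.Series(
                rng.normal(size=16), index=indicator.index))
            _, p = engine.rt(x, 199, rng)
            hits += p <= 0.05
        assert hits >= 90

    def test_type_one_error_brief(self):
        # a short null-calibration check; the full 1000-replicate version
        # lives with the calibration suite
        tree = simulate_tree(12, seed=5)
        engine = SignalEngine(tree)
        rng = np.random.default_rng(1)
        pvals = []
        for _ in range(200):
            _, p = engine.rt(rng.normal(size=12), 99, rng)
            pvals.append(p)
        assert 0.01 <= np.mean(np.array(pvals) < 0.05) <= 0.10


class TestBMSimulation:
    def test_zero_length_tree_stays_at_root(self):
        tree = Phylogeny.from_newick("((A:0,B:0):0,C:0);", is_path=False)
        trait = bm_simulate(tree, sigma2=1.0, root_value=2.5, seed=0)
        assert np.allclose(trait, 2.5)

    def test_moments_match_analytic_covariance(self):
        tree = simulate_tree(6, seed=7)
        cov = tree.vcv()
        X = bm_simulate_batch(tree, sigma2=0.8, seed=8, n=5000)
        emp = np.cov(X.loc[list(cov.labels)].to_numpy())
        expected = 0.8 * cov.matrix
        scale = expected.max()
        assert np.allclose(emp, expected, atol=0.08 * scale)

    def test_deterministic_and_sigma_validated(self):
        tree = simulate_tree(5, seed=0)
        assert bm_simulate(tree, seed=3).equals(bm_simulate(tree, seed=3))
        with pytest.raises(ValueError):
            bm_simulate(tree, sigma2=0.0)


class TestSignalScan:
    def test_single_resource_entire_level(self):
        tree = simulate_tree(8, seed=2)
        sg = pd.DataFrame({"R1": bm_simulate(tree, seed=3)})
        res = signal_scan(tree, sg, n_perm=49, seed=0)
        assert len(res) == 1
        row = res.iloc[0]
        assert row["level"] == "entire" and row["n_tips"] == 8
        assert 0 < row["p_rt"] <= 1

    def test_constant_trait_recorded_not_fatal(self):
        tree = simulate_tree(8, seed=2)
        sg = pd.DataFrame({
            "varies": bm_simulate(tree, seed=4),
            "flat": pd.Series(0.2, index=tree.tips),
        })
        res = signal_scan(tree, sg, n_perm=49, seed=0)
        flat = res[res["resource"] == "flat"].iloc[0]
        assert np.isnan(flat["k_obs"]) and flat["note"] == "constant trait"

    def test_small_groups_skipped(self):
        tree = simulate_tree(12, seed=3)
        sg = pd.DataFrame({"R1": bm_simulate(tree, seed=5)})
        groups = {"tiny": set(list(tree.tips)[:3]),
                  "ok": set(list(tree.tips)[3:])}
        res = signal_scan(tree, sg, groups=groups, n_perm=49, seed=0)
        assert set(res["level"]) == {"entire", "ok"}

    def test_iid_traits_yield_nominal_false_positive_count(self):
        tree = simulate_tree(30, seed=6)
        rng = np.random.default_rng(0)
        counts = []
        for seed in range(3):
            sg = pd.DataFrame(
                rng.normal(size=(30, 95)), index=tree.tips,
                columns=[f"R{j}" for j in range(95)],
            )
            res = signal_scan(tree, sg, n_perm=199, seed=seed)
            counts.append(int((res["p_rt"] < 0.05).sum()))
        assert 0 <= np.mean(counts) <= 12  # ~Binomial(95, .05) mean 4.75

    def test_summary_counts(self):
        tree = simulate_tree(10, seed=8)
        sg = pd.DataFrame({
            "R1": bm_simulate(tree, seed=9),
            "R2": bm_simulate(tree, seed=10),
        })
        labels = pd.Series(["slow"] * 5 + ["fast"] * 5, index=tree.tips)
        res = signal_scan(tree, sg, n_perm=49, seed=0, assemblages=labels)
        summary = summarize_scan(res)
        row = summary.iloc[0]
        assert row["n_resources_tested"] == 2
        assert row["n_slow"] + row["n_fast"] == 10
        assert row["n_k_gt_1"] == int((res["k_obs"] > 1).sum())
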