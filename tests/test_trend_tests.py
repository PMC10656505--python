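import numpy as np
import pandas as pd
import pytest

import coraldepth as cd


class TestPADDeltas:
    def test_sign_convention(self):
        tree = cd.TimeTree.read("(A:1,B:1);")
        vals = np.array([1.5, 2.5, 2.0])  # A, B, root
        out = cd.compute_pad_deltas(tree, {"med": vals})
        row = out.set_index("descendant").loc[0]
        assert row["delta_med"] == pytest.approx(-0.5)
        assert row["direction_med"] == "shallower"

    def test_one_comparison_per_branch(self, medium_tree):
        vals = np.random.default_rng(0).normal(size=medium_tree.n_nodes)
        out = cd.compute_pad_deltas(medium_tree, {"max": vals})
        assert len(out) == medium_tree.n_nodes - 1

    def test_directions_partition(self, medium_tree):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=medium_tree.n_nodes)
        out = cd.compute_pad_deltas(medium_tree, {"med": vals})
        c = out["direction_med"].value_counts()
        assert c.get("shallower", 0) + c.get("deeper", 0) + c.get("none", 0) \
            == len(out)

    def test_missing_depth_rejected(self, small_tree):
        bad = np.full(small_tree.n_nodes, np.nan)
        with pytest.raises(ValueError):
            cd.compute_pad_deltas(small_tree, {"med": bad})


class TestBinomialDirection:
    def test_balanced_split_p_one(self):
        d = np.array([-1.0] * 5 + [1.0] * 5)
        assert cd.binomial_direction_test(d).p_value == pytest.approx(1.0)

    def test_all_deeper_closed_form(self):
        d = np.ones(8)
        assert cd.binomial_direction_test(d).p_value == pytest.approx(2 * 0.5 ** 8)

    def test_majority_shallower_is_significant(self):
        d = np.concatenate([-np.ones(652), np.ones(1018 - 652)])
        r = cd.binomial_direction_test(d)
        assert r.p_value < 0.001
        assert r.extra["percent_shallower"] == pytest.approx(100 * 652 / 1018)

    def test_zero_deltas_excluded_but_counted(self):
        d = np.array([-1.0, 1.0, 0.0, 0.0])
        r = cd.binomial_direction_test(d)
        assert r.n == 2 and r.extra["n_zero"] == 2

    def test_all_zero_is_undefined(self):
        r = cd.binomial_direction_test(np.zeros(4))
        assert r.n == 0 and np.isnan(r.p_value) and r.extra["undefined"]

    @pytest.mark.parametrize("k,n", [(0, 5), (3, 11), (9, 20)])
    def test_matches_tail_sum_oracle(self, k, n):
        from math import comb
        d = np.concatenate([-np.ones(k), np.ones(n - k)])
        pmf = np.array([comb(n, i) * 0.5 ** n for i in range(n + 1)])
        oracle = pmf[pmf <= pmf[k] * (1 + 1e-12)].sum()
        assert cd.binomial_direction_test(d).p_value == pytest.approx(
            min(1.0, oracle), abs=1e-12)

    def test_per_category_table(self, medium_tree):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=medium_tree.n_nodes)
        cats = rng.choice(["AS", "ZC"], size=medium_tree.n_nodes - 1)
        pads = cd.compute_pad_deltas(medium_tree, {"min": vals, "max": vals},
                                     categories=cats)
        out = cd.direction_tests_by_category(pads)
        assert set(out["category"]) == {"all", "AS", "ZC"}
        assert set(out["limit"]) == {"min", "max"}


class TestHolm:
    def test_monotone_and_above_raw(self):
        raw = np.array([0.001, 0.02, 0.04, 0.3, 0.7])
        adj = cd.holm_adjust(raw)
        assert np.all(adj >= raw)
        assert np.all(np.diff(adj[np.argsort(raw)]) >= -1e-12)


class TestPartitionRateComparison:
    def test_standardization_arithmetic(self):
        df = pd.DataFrame({"a": [2.0, 2.0], "b": [4.0, 4.0], "c": [8.0, 8.0]})
        out = cd.compare_partition_rates(df)
        assert np.allclose(out.standardized.iloc[0],
                           [0.0, np.log10(2.0), np.log10(4.0)])

    def test_per_tree_minimum_is_zero_log(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(np.exp(rng.normal(size=(20, 5))),
                          columns=list("abcde"))
        out = cd.compare_partition_rates(df)
        assert np.allclose(out.standardized.min(axis=1), 0.0)

    def test_fast_category_detected(self):
        hits = 0
        for rep in range(5):
            rng = np.random.default_rng(10 + rep)
            base = np.exp(rng.normal(0, 0.3, size=(50, 6)))
            base[:, 2] *= 10.0
            df = pd.DataFrame(base, columns=list("abcdef"))
            out = cd.compare_partition_rates(df)
            top = out.pairwise[out.pairwise["significant"]]
            involves_c = (top["a"] == "c") | (top["b"] == "c")
            hits += int(out.kruskal.p_value < 0.05 and involves_c.sum() == 5)
        assert hits >= 4

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            cd.compare_partition_rates(pd.DataFrame({"a": [1.0, 2.0]}))


class TestLongtermTrends:
    def _nodes(self, n, rng):
        age = rng.uniform(0, 400, n)
        cats = rng.choice(["AS", "ZC"], size=n)
        return age, cats

    def test_negative_depth_age_slope_recovered(self):
        rng = np.random.default_rng(4)
        age, cats = self._nodes(300, rng)
        depth = 3.0 - 0.004 * age + rng.normal(0, 0.1, 300)
        classes = np.where(np.arange(300) % 2 == 0, "constant", "accelerated")
        fits = cd.longterm_trend_regression(depth, age, cats, classes,
                                            n_samples=400, seed=1)
        for fit in fits.values():
            sl = [n for n in fit.coef_names if n.startswith("slope")]
            for name in sl:
                p, sig = fit.crossing_significance(name)
                assert sig and fit.coefficients[name] < 0

    def test_small_category_excluded(self):
        rng = np.random.default_rng(5)
        age = rng.uniform(0, 100, 59)
        cats = np.array(["big"] * 50 + ["small"] * 9)
        depth = rng.normal(size=59)
        classes = np.array(["constant"] * 59)
        fits = cd.longterm_trend_regression(depth, age, cats, classes,
                                            n_samples=200, seed=2)
        names = fits["slow"].coef_names
        assert not any("small" in n for n in names)
        assert any("big" in n for n in names)

    def test_trendless_simulation_not_significant(self):
        flags = []
        for rep in range(5):
            rng = np.random.default_rng(30 + rep)
            age, cats = self._nodes(200, rng)
            depth = rng.normal(2.0, 0.3, 200)
            classes = np.array(["constant"] * 200)
            fits = cd.longterm_trend_regression(depth, age, cats, classes,
                                                n_samples=400, seed=rep)
            fit = fits["slow"]
            sl = [n for n in fit.coef_names if n.startswith("slope")]
            flags.extend(fit.crossing_significance(n)[1] for n in sl)
        assert np.mean(flags) <= 0.2


class TestDepthVsScalar:
    def test_negative_association_recovered(self):
        rng = np.random.default_rng(6)
        depth = rng.uniform(0.5, 3.5, 400)
        r = np.maximum(0.1, 6.0 - 1.5 * depth + rng.normal(0, 0.3, 400))
        cats = np.repeat("AC", 400)
        fit = cd.depth_vs_scalar_regression(depth, r, cats, exclude=(),
                                            n_samples=400, seed=1)
        p, sig = fit.crossing_significance("slope_r_AC")
        assert sig and fit.coefficients["slope_r_AC"] < 0

    def test_constant_scalars_cross_zero(self):
        rng = np.random.default_rng(7)
        depth = rng.uniform(0.5, 3.5, 200)
        with pytest.warns(UserWarning, match="no accelerated"):
            fit = cd.depth_vs_scalar_regression(depth, np.ones(200),
                                                np.repeat("AC", 200),
                                                exclude=(), n_samples=400,
                                                seed=2)
        p, sig = fit.crossing_significance("slope_r_AC")
        assert not sig

    def test_excluded_category_absent(self):
        rng = np.random.default_rng(8)
        depth = rng.uniform(0.5, 3.5, 100)
        r = rng.uniform(1, 5, 100)
        cats = np.array(["ZS"] * 50 + ["AC"] * 50)
        fit = cd.depth_vs_scalar_regression(depth, r, cats)
        assert not any("ZS" in n for n in fit.coef_names)


class TestPathwiseAssociation:
    def _scaled_tree(self, seed):
        tree = cd.simulate_tree(60, 0.1, 0.02, seed=seed)
        rng = np.random.default_rng(seed + 1)
        scal = np.ones(tree.n_nodes)
        scal[: tree.n_nodes - 1] = rng.uniform(0.5, 8.0, tree.n_nodes - 1)
        return tree.with_scalars(scal), rng

    def test_perfect_linear_map_r2_one(self):
        tree, rng = self._scaled_tree(9)
        pw = tree.depths_from_root(use_scalars=True)[tree.tip_ids]
        groups = ["AS"] * tree.n_tips
        y = 2.0 - 0.01 * pw
        fit = cd.pathwise_depth_association(tree, y, groups, lam=0.0,
                                            n_samples=300, seed=1)
        assert fit.r_squared > 0.999

    def test_signal_group_only_detected(self):
        tree, rng = self._scaled_tree(10)
        pw = tree.depths_from_root(use_scalars=True)[tree.tip_ids]
        groups = np.array(["AS", "ZC"])[np.arange(tree.n_tips) % 2]
        y = np.where(groups == "AS", 3.0 - 0.012 * pw,
                     rng.normal(2.0, 0.2, tree.n_tips))
        fit = cd.pathwise_depth_association(tree, y, groups, n_samples=400,
                                            seed=2)
        p_as, sig_as = fit.crossing_significance("slope_pw_AS")
        p_zc, sig_zc = fit.crossing_significance("slope_pw_ZC")
        assert sig_as and fit.coefficients["slope_pw_AS"] < 0
        assert not sig_zc

    def test_pure_bm_mostly_quiet(self):
        flags = []
        for rep in range(4):
            tree = cd.simulate_tree(60, 0.1, 0.02, seed=60 + rep)
            x = cd.simulate_depth(tree, 0.01, 2.5, seed=rep)
            groups = np.array(["AS", "ZC"])[np.arange(tree.n_tips) % 2]
            fit = cd.pathwise_depth_association(tree, x[tree.tip_ids], groups,
                                                n_samples=300, seed=rep)
            for name in [n for n in fit.coef_names if n.startswith("slope")]:
                flags.append(fit.crossing_significance(name)[1])
        assert np.mean(flags) <= 0.25
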