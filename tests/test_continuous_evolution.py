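import math

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

import coraldepth as cd
from coraldepth.continuous_evolution import gls_marginal_loglik


class TestBMLoglik:
    def test_two_tip_zero_values(self):
        t = cd.TimeTree.read("(A:1,B:1);")
        ll = cd.bm_loglik(t, {"A": 0.0, "B": 0.0}, sigma2=1.0, root_mean=0.0)
        assert ll == pytest.approx(-math.log(2 * math.pi), abs=1e-9)

    def test_two_tip_quadratic_form(self):
        t = cd.TimeTree.read("(A:1,B:1);")
        ll = cd.bm_loglik(t, {"A": 1.0, "B": -1.0}, sigma2=1.0, root_mean=0.0)
        assert ll == pytest.approx(-math.log(2 * math.pi) - 1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_dense_mvn_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        t = cd.simulate_tree(n, 0.3, 0.1, seed=seed + 100)
        t.scalar[: t.n_nodes - 1] = rng.uniform(0.2, 5.0, t.n_nodes - 1)
        y = rng.normal(size=n)
        lam = float(rng.uniform(0, 1))
        s2, mu = float(rng.uniform(0.3, 2.0)), float(rng.normal())
        V = cd.tip_covariance(t, lam=lam)
        oracle = multivariate_normal.logpdf(y, mean=np.full(n, mu), cov=s2 * V)
        assert cd.bm_loglik(t, y, s2, mu, lam=lam) == pytest.approx(oracle, abs=1e-8)

    def test_rescaling_invariance(self, small_tree):
        rng = np.random.default_rng(1)
        y = rng.normal(size=small_tree.n_tips)
        a = cd.bm_loglik(small_tree, y, sigma2=0.8, root_mean=0.0)
        scaled = cd.TimeTree(small_tree.parent, small_tree.length * 4.0,
                             small_tree.labels)
        b = cd.bm_loglik(scaled, y, sigma2=0.2, root_mean=0.0)
        assert a == pytest.approx(b, abs=1e-10)

    def test_lambda_zero_means_independent_tips(self, small_tree):
        rng = np.random.default_rng(2)
        y = rng.normal(size=small_tree.n_tips)
        depths = small_tree.depths_from_root()[small_tree.tip_ids]
        expected = norm.logpdf(y, loc=0.5, scale=np.sqrt(0.7 * depths)).sum()
        assert cd.bm_loglik(small_tree, y, 0.7, 0.5, lam=0.0) == pytest.approx(
            expected, abs=1e-9)

    def test_missing_tip_value_raises(self, small_tree):
        vals = {l: 0.0 for l in small_tree.tip_labels[:-1]}
        with pytest.raises(ValueError):
            cd.bm_loglik(small_tree, vals, 1.0, 0.0)


class TestDesignMatrix:
    def test_plain_species_one_hot(self):
        X = cd.build_design_matrix(["ZC", "AS"])
        assert X[0].tolist() == [0, 0, 0, 1]
        assert X[1].tolist() == [1, 0, 0, 0]

    def test_facultative_symbiosis_splits_half_half(self):
        # colonial species facultative for symbiosis: 0.5 in AC and ZC
        X = cd.build_design_matrix(["ZC"], ["symbiosis"])
        assert X[0].tolist() == [0, 0.5, 0, 0.5]

    def test_facultative_coloniality(self):
        X = cd.build_design_matrix(["AS"], ["coloniality"])
        assert X[0].tolist() == [0.5, 0.5, 0, 0]

    def test_rows_sum_to_one(self):
        X = cd.build_design_matrix(["AS", "ZC", "AC"],
                                   [None, "symbiosis", "coloniality"])
        assert np.allclose(X.sum(axis=1), 1.0)

    def test_unknown_group_raises(self):
        with pytest.raises(ValueError):
            cd.build_design_matrix(["XX"])


class TestPGLS:
    def test_perfect_fit_recovers_slope_and_r2(self, medium_tree):
        rng = np.random.default_rng(3)
        x = rng.normal(size=medium_tree.n_tips)
        y = 2.0 * x
        X = np.column_stack([np.ones_like(x), x])
        fit = cd.pgls_regression(medium_tree, y, X, lam=0.0, n_samples=400, seed=0)
        assert fit.coefficients["b1"] == pytest.approx(2.0, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_lambda_zero_matches_ols_oracle(self, medium_tree):
        rng = np.random.default_rng(4)
        x = rng.normal(size=medium_tree.n_tips)
        y = 1.0 + 0.5 * x + rng.normal(scale=0.3, size=x.size)
        X = np.column_stack([np.ones_like(x), x])
        # ultrametric tree, lambda 0 -> V proportional to I -> GLS == OLS
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        fit = cd.pgls_regression(medium_tree, y, X, lam=0.0, n_samples=3000, seed=1)
        est = np.mean(fit.beta_samples, axis=0)
        se = np.std(fit.beta_samples, axis=0) / math.sqrt(len(fit.beta_samples))
        # posterior mean equals the OLS point estimate up to Monte-Carlo error
        assert np.all(np.abs(est - beta_ols) < 5 * se + 1e-6)

    def test_rank_deficient_design_raises(self, small_tree):
        X = np.ones((small_tree.n_tips, 2))
        with pytest.raises(ValueError):
            cd.pgls_regression(small_tree, np.arange(small_tree.n_tips, dtype=float), X)


class TestVariableRates:
    def test_all_unit_scalars_reduce_to_bm(self, small_tree):
        """With births suppressed the chain stays at r = 1 everywhere and its
        conditional likelihood is exactly the Brownian pruning likelihood."""
        rng = np.random.default_rng(5)
        y = rng.normal(loc=3.0, scale=0.5, size=small_tree.n_tips)
        cfg = cd.VRConfig(n_iter=30, burn_in=0, thin=1, seed=2,
                          geometric_p=1 - 1e-12)
        chain = cd.vr_rjmcmc(small_tree, y, config=cfg)
        assert np.all(chain.n_scalars == 0)
        V = cd.tip_covariance(small_tree)
        for s in range(chain.scalars.shape[0]):
            dense = multivariate_normal.logpdf(
                y, mean=np.full(small_tree.n_tips, chain.beta[s, 0]),
                cov=chain.sigma2[s] * V)
            assert chain.loglik[s] == pytest.approx(dense, abs=1e-10)

    def test_constant_response_raises(self, small_tree):
        with pytest.raises(ValueError):
            cd.vr_rjmcmc(small_tree, np.zeros(small_tree.n_tips))

    def test_accelerated_clade_detected(self):
        tree = cd.simulate_tree(80, 0.08, 0.02, seed=7)
        tb = tree.tips_below()
        clade = next(i for i in range(tree.n_nodes - 1)
                     if not tree.is_tip[i] and 8 <= len(tb[i]) <= 20)
        nodes = tree.clade_nodes(clade)
        x = cd.simulate_depth(tree, 0.01, 3.0, seed=11,
                              scalar_map={int(b): 25.0 for b in nodes})
        cfg = cd.VRConfig(n_iter=5000, burn_in=1200, thin=10, seed=1)
        chain = cd.vr_rjmcmc(tree, x[tree.tip_ids], config=cfg)
        scaled, classes = cd.summarize_scaled_tree(chain)
        assert np.median(scaled.scalar[nodes]) > 2.0
        assert (classes[nodes] == "accelerated").mean() > 0.5


class TestScaledTreeSummary:
    def _chain(self, scalars):
        tree = cd.TimeTree.read("(A:1,B:1);")
        S = scalars.shape[0]
        return cd.PosteriorChain(
            tree=tree, scalars=scalars, beta=np.zeros((S, 1)),
            sigma2=np.ones(S), loglik=np.zeros(S), marginal_ll=np.zeros(S),
            n_scalars=np.zeros(S, dtype=int), coef_names=["root_mean"],
            seed=0, accept_rate=0.0)

    def test_present_and_large_scalar_kept(self):
        scal = np.ones((10, 3))
        scal[:6, 0] = 3.0  # scaled in 60% of samples, median 3
        tree, classes = cd.summarize_scaled_tree(self._chain(scal))
        assert tree.scalar[0] == pytest.approx(3.0)
        assert classes[0] == "accelerated"

    def test_below_presence_threshold_reset(self):
        scal = np.ones((10, 3))
        scal[:4, 0] = 3.0  # only 40%
        tree, classes = cd.summarize_scaled_tree(self._chain(scal))
        assert tree.scalar[0] == 1.0
        assert classes[0] == "constant"

    def test_below_magnitude_threshold_reset(self):
        scal = np.ones((10, 3))
        scal[:9, 0] = 1.5  # present but too small
        tree, _ = cd.summarize_scaled_tree(self._chain(scal))
        assert tree.scalar[0] == 1.0

    def test_symmetric_compression_rule(self):
        scal = np.ones((10, 3))
        scal[:8, 0] = 0.2
        tree, classes = cd.summarize_scaled_tree(self._chain(scal))
        assert tree.scalar[0] == pytest.approx(0.2)
        assert classes[0] == "decelerated"


class TestPartitionedRates:
    def test_single_category_is_global_rescaling(self, small_tree):
        """One global scalar r trades off exactly against sigma2: the scaled
        likelihood equals the plain BM likelihood at sigma2 * r."""
        rng = np.random.default_rng(6)
        y = rng.normal(size=small_tree.n_tips)
        r = 3.7
        scaled = small_tree.with_scalars(np.full(small_tree.n_nodes, r))
        a = cd.bm_loglik(scaled, y, sigma2=0.5, root_mean=0.0)
        b = cd.bm_loglik(small_tree, y, sigma2=0.5 * r, root_mean=0.0)
        assert a == pytest.approx(b, abs=1e-10)

    def test_two_partition_ratio_recovery(self):
        tree = cd.simulate_tree(100, 0.08, 0.02, seed=41)
        part = np.array(["slow"] * (tree.n_nodes - 1), dtype=object)
        tb = tree.tips_below()
        clade = next(i for i in range(tree.n_nodes - 1)
                     if not tree.is_tip[i] and 30 <= len(tb[i]) <= 50)
        nodes = tree.clade_nodes(clade)
        part[nodes[nodes < tree.n_nodes - 1]] = "fast"
        smap = {int(b): 10.0 for b in nodes if b < tree.n_nodes - 1}
        x = cd.simulate_depth(tree, 0.01, 3.0, seed=1, scalar_map=smap)
        rates = cd.partitioned_rates(
            tree, x[tree.tip_ids], part,
            cd.VRConfig(n_iter=3000, burn_in=800, thin=5, seed=1))
        ratio = np.median(rates["fast"]) / np.median(rates["slow"])
        assert 5.0 <= ratio <= 20.0


class TestSteppingStone:
    def _toy(self):
        return cd.SteppingStoneModel(
            sample_prior=lambda rng: rng.normal(0, 1, size=1),
            log_prior=lambda th: -0.5 * th[0] ** 2 - 0.5 * math.log(2 * math.pi),
            log_likelihood=lambda th: -0.5 * th[0] ** 2 - 0.5 * math.log(2 * math.pi),
            proposal_sd=1.0)

    def test_constant_likelihood_is_exact(self):
        m = cd.SteppingStoneModel(
            sample_prior=lambda rng: rng.normal(0, 1, size=1),
            log_prior=lambda th: -0.5 * th[0] ** 2 - 0.5 * math.log(2 * math.pi),
            log_likelihood=lambda th: -3.21, proposal_sd=1.0)
        est = cd.stepping_stone_logml(m, n_stones=8, iters_per_stone=50, seed=0)
        assert est.logml == pytest.approx(-3.21, abs=1e-12)

    def test_conjugate_normal_toy(self):
        target = -0.5 * math.log(4 * math.pi)
        ests = [cd.stepping_stone_logml(self._toy(), 32, 400, seed=s).logml
                for s in range(10)]
        assert abs(np.mean(ests) - target) < 0.05

    def test_more_stones_reduce_spread(self):
        coarse = [cd.stepping_stone_logml(self._toy(), 4, 150, seed=s).logml
                  for s in range(8)]
        fine = [cd.stepping_stone_logml(self._toy(), 64, 150, seed=s).logml
                for s in range(8)]
        assert np.std(fine) < np.std(coarse)


class TestModelComparison:
    def test_very_strong_evidence(self):
        mc = cd.log_bayes_factor(-100.0, -110.0)
        assert mc.log_bf == pytest.approx(20.0)
        assert mc.evidence == "very strong"

    def test_equal_models(self):
        assert cd.log_bayes_factor(-5.0, -5.0).log_bf == 0.0

    def test_negative_favors_simple(self):
        mc = cd.log_bayes_factor(-110.0, -100.0)
        assert mc.log_bf == pytest.approx(-20.0)
        assert mc.evidence == "favors simple"


class TestCrossingSignificance:
    def test_all_positive_is_significant(self):
        p, sig = cd.posterior_crossing_significance(np.abs(np.random.default_rng(0)
                                                           .normal(size=500)) + 0.1)
        assert p == 0.0 and sig

    def test_symmetric_not_significant(self):
        x = np.concatenate([np.arange(1, 201), -np.arange(1, 201)])
        p, sig = cd.posterior_crossing_significance(x)
        assert p == pytest.approx(0.5)
        assert not sig

    def test_normal_tail_boundary(self):
        rng = np.random.default_rng(7)
        x = rng.normal(loc=1.645, scale=1.0, size=200_000)
        p, _ = cd.posterior_crossing_significance(x)
        assert p == pytest.approx(norm.cdf(-1.645), abs=0.005)

    def test_too_few_samples_raises(self):
        with pytest.raises(ValueError):
            cd.posterior_crossing_significance(np.ones(50))


def test_gls_marginal_consistent_under_data_scaling(small_tree):
    """Scaling y by c shifts the marginal by -n/2 * log(c^2) exactly (flat
    prior on coefficients, Jeffreys on sigma2)."""
    rng = np.random.default_rng(8)
    y = rng.normal(size=small_tree.n_tips)
    X = np.ones((small_tree.n_tips, 1))
    V = cd.tip_covariance(small_tree)
    c = 3.0
    a = gls_marginal_loglik(V, X, y)
    b = gls_marginal_loglik(V, X, c * y)
    n, k = small_tree.n_tips, 1
    assert b - a == pytest.approx(-(n - k) * math.log(c) + k * 0.0, abs=1e-8)


class TestDiagnostics:
    def test_well_mixed_chains_pass(self):
        rng = np.random.default_rng(11)
        d = cd.convergence_diagnostics([rng.normal(size=400),
                                        rng.normal(size=400)])
        assert d["ess"] > 100
        assert abs(d["r_hat"] - 1.0) < 0.05

    def test_divergent_chains_flagged(self):
        rng = np.random.default_rng(12)
        d = cd.convergence_diagnostics([rng.normal(0, 1, 400),
                                        rng.normal(10, 1, 400)])
        assert d["r_hat"] > 1.5

    def test_multi_chain_runner_gives_distinct_seeds(self, small_tree):
        rng = np.random.default_rng(13)
        y = rng.normal(size=small_tree.n_tips)
        chains = cd.vr_rjmcmc_chains(
            small_tree, y, config=cd.VRConfig(n_iter=200, burn_in=50, thin=5),
            n_chains=2)
        assert len(chains) == 2
        assert chains[0].seed != chains[1].seed
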