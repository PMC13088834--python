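import numpy as np
import pytest
from scipy import integrate, stats

from emanova._trace_moments import MomentEngine
from emanova.base_test import (
    DegenerateDesignError,
    DegenerateNullError,
    base_statistic,
    pearson3_pvalue,
    permutation_moments,
    projection_matrices,
    run_base_test,
    skewness,
)
from emanova.kernel import centered_kernel, psd_fix
from emanova.distances import bray_curtis
from emanova.perm_oracle import exhaustive_moments, mc_permutation_pvalue
from emanova.simulate import SimulationConfig, simulate_dataset
from tests.conftest import centered_random_matrix


class TestProjectionMatrices:
    def test_nested_design_gives_zero_contrast(self, rng):
        X2 = rng.standard_normal((10, 2))
        X1 = X2 @ rng.standard_normal((2, 1))  # X1 inside span(X2)
        proj = projection_matrices(X1, X2)
        np.testing.assert_allclose(proj.G, 0.0, atol=1e-10)
        assert proj.v == 0

    def test_single_covariate_rank_one_idempotent(self, rng):
        x = rng.standard_normal(12)
        x -= x.mean()
        proj = projection_matrices(x[:, None])
        assert proj.v == 1
        np.testing.assert_allclose(proj.G @ proj.G, proj.G, atol=1e-10)
        np.testing.assert_allclose(proj.G.sum(axis=1), 0.0, atol=1e-10)

    def test_duplicate_column_changes_nothing(self, rng):
        X1 = rng.standard_normal((15, 2))
        X1 -= X1.mean(axis=0)
        base = projection_matrices(X1)
        dup = projection_matrices(np.hstack([X1, X1[:, :1]]))
        np.testing.assert_allclose(base.G, dup.G, atol=1e-8)

    def test_overparameterized_rejected(self, rng):
        with pytest.raises(ValueError):
            projection_matrices(rng.standard_normal((4, 5)))


class TestBaseStatistic:
    def test_zero_contrast_gives_zero(self, rng):
        K = centered_random_matrix(5, rng)
        assert base_statistic(np.zeros((5, 5)), K) == 0.0

    def test_matches_double_loop(self, rng):
        G = centered_random_matrix(4, rng)
        K = centered_random_matrix(4, rng)
        naive = sum(
            G[i, j] * K[i, j] for i in range(4) for j in range(4)
        )
        assert base_statistic(G, K) == pytest.approx(naive, abs=1e-10)
        assert base_statistic(G, K) == pytest.approx(np.trace(G @ K), abs=1e-10)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            base_statistic(np.zeros((3, 3)), np.zeros((4, 4)))


class TestPermutationMoments:
    """Closed-form moments vs. the exhaustive n! enumeration oracle."""

    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_exact_against_enumeration(self, n, rng):
        for _ in range(4):
            G = centered_random_matrix(n, rng)
            K = psd_fix(centered_random_matrix(n, rng))
            analytic = permutation_moments(G, K)
            exact = exhaustive_moments(G, K)
            for a, e in zip(analytic, exact):
                assert a == pytest.approx(e, rel=1e-10, abs=1e-10)

    def test_zero_kernel_gives_zero_moments(self, rng):
        G = centered_random_matrix(5, rng)
        assert permutation_moments(G, np.zeros((5, 5))) == (0.0, 0.0, 0.0)

    def test_mean_identity(self, rng):
        # E[T] = tr(G) tr(K) / (n-1) for double-centered inputs
        n = 6
        G = centered_random_matrix(n, rng)
        K = psd_fix(centered_random_matrix(n, rng))
        E1, _, _ = permutation_moments(G, K)
        assert E1 == pytest.approx(np.trace(G) * np.trace(K) / (n - 1), rel=1e-10)

    def test_invariant_kernel_has_zero_variance(self, rng):
        # the centering projector H is permutation-invariant: P H P' = H
        n = 5
        H = np.eye(n) - 1.0 / n
        G = centered_random_matrix(n, rng)
        E1, Var, _ = permutation_moments(G, H)
        assert Var == pytest.approx(0.0, abs=1e-12)
        assert E1 == pytest.approx(np.trace(G), rel=1e-10)

    def test_non_centered_input_rejected(self, rng):
        A = rng.standard_normal((5, 5))
        with pytest.raises(ValueError, match="double-centered"):
            permutation_moments(A + A.T, centered_random_matrix(5, rng))

    def test_monte_carlo_consistency_large_n(self, rng):
        # closed form within 4 standard errors of sampled-permutation moments
        n = 100
        G = projection_matrices(centered_random_matrix(n, rng)[:, 0][:, None]).G
        K = psd_fix(centered_random_matrix(n, rng))
        E1, Var, E3 = permutation_moments(G, K)
        B = 100_000
        idx = np.argsort(rng.random((B, n)), axis=1)
        ts = np.empty(B)
        for s in range(0, B, 500):
            chunk = idx[s : s + 500]
            Kp = K[chunk[:, :, None], chunk[:, None, :]]
            ts[s : s + 500] = np.einsum("bij,ij->b", Kp, G)
        se_mean = ts.std() / np.sqrt(B)
        assert abs(E1 - ts.mean()) < 4 * se_mean
        assert abs(Var - ts.var()) < 4 * np.sqrt(((ts - ts.mean()) ** 4).mean() / B)
        m3 = (ts**3).mean()
        assert abs(E3 - m3) < 4 * (ts**3).std() / np.sqrt(B)


class TestSkewness:
    def test_plug_in_values(self):
        assert skewness(0.0, 1.0, 2.0) == pytest.approx(2.0)
        assert skewness(0.0, 1.0, 0.0) == pytest.approx(0.0)

    def test_matches_exhaustive_sample_skewness(self, rng):
        n = 5
        G = centered_random_matrix(n, rng)
        K = psd_fix(centered_random_matrix(n, rng))
        E1, Var, E3 = exhaustive_moments(G, K)
        gamma_closed = skewness(*permutation_moments(G, K))
        gamma_exact = (E3 - 3 * E1 * Var - E1**3) / Var**1.5
        assert gamma_closed == pytest.approx(gamma_exact, abs=1e-8)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(DegenerateNullError):
            skewness(1.0, 0.0, 1.0)


class TestPearson3Pvalue:
    def test_symmetric_limit_at_zero(self):
        assert pearson3_pvalue(0.0, 0.0, 1.0, 0.0) == pytest.approx(0.5)

    def test_lower_support_endpoint_gives_one(self):
        gamma = 1.0  # b = 4, support starts at -2
        p = pearson3_pvalue(-2.0, 0.0, 1.0, gamma)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_printed_value_gamma_one(self):
        # b=4: survival of the shifted gamma at t=2 is exp(-8) * sum_{k<4} 8^k/k!
        p = pearson3_pvalue(2.0, 0.0, 1.0, 1.0)
        import math

        expected = np.exp(-8) * sum(8.0**k / math.factorial(k) for k in range(4))
        assert p == pytest.approx(expected, rel=1e-10)
        assert p == pytest.approx(0.0424, abs=5e-5)

    @pytest.mark.parametrize("gamma", [-1.5, -0.6, 0.6, 1.5])
    @pytest.mark.parametrize("t", [-1.0, 0.0, 0.5, 2.0])
    def test_matches_density_integration(self, gamma, t):
        # numerical integration of the Pearson III density with the
        # (scale, shape, location) parametrization
        b = 4.0 / gamma**2
        sb = np.sqrt(b)
        if gamma > 0:
            dens = lambda x: stats.gamma.pdf(x + sb, a=b, scale=1.0 / sb)
            val, _ = integrate.quad(dens, t, np.inf, limit=200)
        else:
            dens = lambda x: stats.gamma.pdf(sb - x, a=b, scale=1.0 / sb)
            val, _ = integrate.quad(dens, t, sb, limit=200)
        assert pearson3_pvalue(t, 0.0, 1.0, gamma) == pytest.approx(val, abs=1e-8)

    @pytest.mark.parametrize("gamma", [-0.8, 0.0, 0.8])
    def test_matches_scipy_pearson3(self, gamma):
        # independent cross-check against scipy's standardized Pearson III
        for t in (-1.5, 0.0, 1.0, 3.0):
            mine = pearson3_pvalue(t, 0.0, 1.0, gamma)
            ref = float(stats.pearson3.sf(t, skew=gamma)) if gamma != 0 else float(
                stats.norm.sf(t)
            )
            assert mine == pytest.approx(ref, abs=1e-10)

    def test_monotone_in_statistic(self):
        ps = [pearson3_pvalue(t, 0.0, 1.0, 0.7) for t in np.linspace(-3, 6, 40)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_clipping_bounds(self):
        assert pearson3_pvalue(1e6, 0.0, 1.0, 1.0) >= 1e-15
        assert pearson3_pvalue(-1e6, 0.0, 1.0, -1.0) <= 1 - 1e-15


@pytest.fixture(scope="module")
def dataset():
    return simulate_dataset(SimulationConfig(n=50, K=80, scenario="S2",
                                             beta=0.6, seed=4))


class TestRunBaseTest:

    def test_pvalue_close_to_monte_carlo(self, dataset):
        ds = dataset
        y = ds.y - ds.y.mean()
        res = run_base_test(ds.table, ds.tree, y[:, None], None, d=3, r=1.0)
        proj = projection_matrices(y[:, None])
        ck = centered_kernel(bray_curtis(ds.table))
        B = 10_000
        p_mc = mc_permutation_pvalue(proj.G, ck.power(1.0), B=B, seed=1)
        se = np.sqrt(p_mc * (1 - p_mc) / B)
        # the three-moment fit carries an intrinsic body error of a few 1e-3,
        # on top of the Monte Carlo noise of the reference itself
        assert abs(res.pvalue - p_mc) <= max(0.01, 3 * se)

    def test_relabeling_invariance(self, dataset):
        ds = dataset
        y = ds.y - ds.y.mean()
        base = run_base_test(ds.table, ds.tree, y[:, None], None, d=3, r=0.5)
        perm = np.random.default_rng(3).permutation(ds.table.n_samples)
        shuffled = ds.table.select_samples(
            [ds.table.sample_ids[i] for i in perm]
        )
        again = run_base_test(shuffled, ds.tree, y[perm][:, None], None, d=3, r=0.5)
        assert again.T == pytest.approx(base.T, abs=1e-10)
        assert again.pvalue == pytest.approx(base.pvalue, abs=1e-10)

    def test_tree_required_for_unifrac(self, dataset):
        ds = dataset
        with pytest.raises(ValueError, match="tree"):
            run_base_test(ds.table, None, ds.y[:, None] - ds.y.mean(), None,
                          d=1, r=1.0)

    def test_degenerate_design_rejected(self, dataset):
        ds = dataset
        X2 = np.column_stack([ds.X2 - ds.X2.mean()])
        with pytest.raises(DegenerateDesignError):
            run_base_test(ds.table, ds.tree, X2.copy(), X2, d=3, r=1.0)

    def test_null_pvalues_uniform(self):
        # beta = 0: base p-values over replicates should be ~ Uniform(0,1)
        cfg = SimulationConfig(n=40, K=60, scenario="S2", beta=0.0, seed=8)
        ss = np.random.SeedSequence(8)
        from emanova.simulate import simulate_tree, simulate_dataset as sim

        tree = simulate_tree(cfg.K, 99)
        pvals = []
        for child in ss.spawn(500):
            rng = np.random.default_rng(child)
            ds = sim(cfg, tree=tree, rng=rng)
            y = ds.y - ds.y.mean()
            X2 = np.column_stack([ds.X1 - ds.X1.mean(), ds.X2 - ds.X2.mean()])
            proj = projection_matrices(y[:, None], X2)
            ck = centered_kernel(bray_curtis(ds.table))
            Kr = ck.power(1.0)
            E1, Var, E3 = MomentEngine(proj.G).moments(Kr)
            g = skewness(E1, Var, E3)
            pvals.append(pearson3_pvalue(base_statistic(proj.G, Kr), E1, Var, g))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
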