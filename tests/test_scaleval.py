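import numpy as np
import pytest
from scipy.stats import multivariate_normal

from actipain.scaleval import (
    FactorSolution,
    OrdinalItemMatrix,
    ValidationConfig,
    bvn_cdf,
    fit_factor_model,
    internal_consistency,
    parallel_analysis,
    polychoric_corr,
    polychoric_matrix,
    prune_items,
)


def graded_items(rng, n, loadings, cuts=(-1.0, 0.0, 1.0), n_factors=1, assign=None):
    """One- or two-factor graded ordinal responses with standard-normal noise."""
    loadings = np.asarray(loadings, dtype=float)
    p = len(loadings)
    theta = rng.standard_normal((n, n_factors))
    if assign is None:
        assign = np.zeros(p, dtype=int)
    Z = theta[:, assign] * loadings + rng.standard_normal((n, p))
    return np.digitize(Z, cuts)


class TestBvnCdf:
    def test_matches_scipy_reference(self, rng):
        for rho in (-0.9, -0.3, 0.0, 0.5, 0.95):
            pts = rng.normal(size=(10, 2)) * 1.5
            ours = bvn_cdf(pts[:, 0], pts[:, 1], rho)
            mvn = multivariate_normal([0, 0], [[1, rho], [rho, 1]])
            ref = np.array([mvn.cdf(p) for p in pts])
            np.testing.assert_allclose(ours, ref, atol=1e-10)


class TestPolychoric:
    def test_identical_items_clamp(self, rng):
        x = rng.integers(0, 4, 500)
        assert polychoric_corr(x, x) == pytest.approx(0.999, abs=2e-3)

    def test_independent_items_near_zero(self, rng):
        n = 5000
        x = rng.integers(0, 5, n)
        y = rng.integers(0, 5, n)
        # polychoric SE is a small multiple of 1/sqrt(n)
        assert abs(polychoric_corr(x, y)) < 3 * 1.5 / np.sqrt(n)

    def test_latent_rho_recovery_at_tertiles(self, rng):
        """Latent bivariate normal rho=0.5 cut at tertiles, n=20,000."""
        n = 20_000
        z = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], n)
        cuts = [-0.4307, 0.4307]
        rho = polychoric_corr(np.digitize(z[:, 0], cuts), np.digitize(z[:, 1], cuts))
        assert rho == pytest.approx(0.5, abs=3 * 1.3 / np.sqrt(n))

    def test_row_permutation_invariance(self, rng):
        X = graded_items(rng, 200, np.full(4, 0.6))
        items = OrdinalItemMatrix(X)
        perm = OrdinalItemMatrix(X[rng.permutation(len(X))])
        np.testing.assert_allclose(
            polychoric_matrix(items), polychoric_matrix(perm), atol=1e-8
        )

    def test_single_category_item_named(self):
        X = np.column_stack([np.ones(50, int), np.arange(50) % 3])
        with pytest.raises(ValueError, match="item_0"):
            OrdinalItemMatrix(X)


class TestParallelAnalysis:
    def test_one_factor_data(self, rng):
        X = graded_items(rng, 500, np.full(10, 0.7))
        assert parallel_analysis(OrdinalItemMatrix(X), ValidationConfig(seed=0)) == 1

    def test_two_orthogonal_factors(self, rng):
        assign = np.r_[np.zeros(5, int), np.ones(5, int)]
        X = graded_items(rng, 1000, np.full(10, 0.8), n_factors=2, assign=assign)
        assert parallel_analysis(OrdinalItemMatrix(X), ValidationConfig(seed=0)) == 2

    def test_pure_noise_returns_zero_with_p95(self, rng):
        """Under independence the observed eigenvalues share the criterion's
        null distribution, so the 95th-percentile criterion retains nothing."""
        hits = 0
        for s in range(10):
            X = rng.integers(0, 4, size=(500, 10))
            cfg = ValidationConfig(seed=s, parallel_criterion="p95")
            hits += parallel_analysis(OrdinalItemMatrix(X), cfg) == 0
        assert hits >= 8

    def test_count_nonincreasing_as_loadings_shrink(self, rng):
        counts = []
        for lam in (0.8, 0.4, 0.0):
            X = graded_items(rng, 600, np.full(8, lam))
            cfg = ValidationConfig(seed=3, parallel_criterion="p95")
            counts.append(parallel_analysis(OrdinalItemMatrix(X), cfg))
        assert counts[0] >= counts[1] >= counts[2]

    def test_too_few_comparison_datasets(self, rng):
        X = graded_items(rng, 100, np.full(4, 0.5))
        with pytest.raises(ValueError):
            parallel_analysis(OrdinalItemMatrix(X), ValidationConfig(n_parallel_datasets=10))


class TestFactorModel:
    def test_identity_matrix_no_common_variance(self):
        sol = fit_factor_model(np.eye(6), 1)
        assert np.abs(sol.loadings).max() < 0.05

    def test_rank_one_recovery(self):
        lam = np.full(8, 0.8)
        R = np.outer(lam, lam)
        np.fill_diagonal(R, 1.0)
        sol = fit_factor_model(R, 1)
        np.testing.assert_allclose(np.abs(sol.loadings[:, 0]), 0.8, atol=1e-3)

    def test_oblique_two_factor_recovery(self):
        L = np.zeros((10, 2))
        L[:5, 0] = L[5:, 1] = 0.8
        Phi = np.array([[1.0, 0.4], [0.4, 1.0]])
        R = L @ Phi @ L.T
        np.fill_diagonal(R, 1.0)
        sol = fit_factor_model(R, 2)
        assert sol.factor_correlations[0, 1] == pytest.approx(0.4, abs=0.05)
        main = np.sort(np.abs(sol.loadings).max(axis=1))
        np.testing.assert_allclose(main, 0.8, atol=0.02)

    def test_rotation_preserves_model_fit(self, rng):
        X = graded_items(
            rng, 800, np.full(10, 0.7), n_factors=2,
            assign=np.r_[np.zeros(5, int), np.ones(5, int)],
        )
        R = polychoric_matrix(OrdinalItemMatrix(X))
        unrot_common = None
        sol = fit_factor_model(R, 2)
        common = sol.loadings @ sol.factor_correlations @ sol.loadings.T
        resid = R - common
        np.fill_diagonal(resid, 0.0)
        # Lambda Phi Lambda' reproduces the off-diagonal structure as well
        # as any 2-factor model can; rotation must not change it
        sol_b = fit_factor_model(R, 2)
        common_b = sol_b.loadings @ sol_b.factor_correlations @ sol_b.loadings.T
        np.testing.assert_allclose(common, common_b, atol=1e-6)

    def test_too_many_factors_rejected(self):
        with pytest.raises(ValueError):
            fit_factor_model(np.eye(4), 4)


class TestPruning:
    def test_strong_items_nothing_removed(self, rng):
        X = graded_items(rng, 600, np.full(8, 0.7))
        sol = prune_items(OrdinalItemMatrix(X), ValidationConfig(seed=0), n_factors=1)
        assert sol.removed_items == []
        assert len(sol.retained_items) == 8

    def test_planted_weak_item_removed_first(self, rng):
        loadings = np.full(9, 0.7)
        loadings[4] = 0.05
        X = graded_items(rng, 800, loadings)
        sol = prune_items(OrdinalItemMatrix(X), ValidationConfig(seed=0), n_factors=1)
        assert sol.removed_items[0] == "item_4"
        assert "item_4" not in sol.retained_items

    def test_isizulu_scale_curtailment_emulation(self, rng):
        """25 items with 2 unrelated ones: pruning retains 23, the count of
        the truncated translated Resilience Scale."""
        loadings = np.full(25, 0.7)
        loadings[[7, 19]] = 0.02
        X = graded_items(rng, 600, loadings, cuts=(-1.5, -0.5, 0.5, 1.5))
        sol = prune_items(OrdinalItemMatrix(X), ValidationConfig(seed=1), n_factors=1)
        assert len(sol.retained_items) == 23
        assert set(sol.removed_items) == {"item_7", "item_19"}

    def test_idempotent_on_retained_set(self, rng):
        loadings = np.full(9, 0.7)
        loadings[2] = 0.05
        X = graded_items(rng, 800, loadings)
        items = OrdinalItemMatrix(X)
        first = prune_items(items, ValidationConfig(seed=0), n_factors=1)
        again = prune_items(
            items.subset(first.retained_items), ValidationConfig(seed=0), n_factors=1
        )
        assert again.removed_items == []

    def test_refuses_to_prune_below_three_items(self, rng):
        X = rng.integers(0, 5, size=(300, 3))  # all noise: everything offends
        with pytest.raises(ValueError, match="fewer than 3"):
            prune_items(OrdinalItemMatrix(X), ValidationConfig(seed=0), n_factors=1)


class TestInternalConsistency:
    def test_identical_items_alpha_one(self, rng):
        x = rng.integers(0, 5, 200)
        raw, ordinal = internal_consistency(OrdinalItemMatrix(np.column_stack([x, x, x])))
        assert raw == pytest.approx(1.0) and ordinal == pytest.approx(1.0, abs=0.01)

    def test_independent_items_alpha_near_zero(self, rng):
        X = rng.integers(0, 5, size=(5000, 6))
        raw, _ = internal_consistency(OrdinalItemMatrix(X))
        assert abs(raw) < 0.1

    def test_spearman_brown_closed_form(self, rng):
        """k=25 items with latent loading 0.7: inter-item latent correlation
        0.7^2/(1+0.7^2)... on the latent-response scale each pair correlates
        at rho = 0.49/1.49; ordinal alpha follows Spearman-Brown."""
        lam = 0.7
        k, n = 25, 5000
        X = graded_items(rng, n, np.full(k, lam))
        rho = lam**2 / (1 + lam**2)
        expected = k * rho / (1 + (k - 1) * rho)
        _, ordinal = internal_consistency(OrdinalItemMatrix(X))
        assert ordinal == pytest.approx(expected, abs=0.02)
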