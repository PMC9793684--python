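"""Behavior imputation, PCA reduction, canonical correlation and its
out-of-sample robustness machinery."""

import numpy as np
import pandas as pd
import pytest

from taskpotency.behavior import BEHAVIOR_SCALES, impute_behavior_rf
from taskpotency.cca import (
    BrainBehaviorCCA,
    assess_significance,
    backproject_brain_weights,
    canonical_loadings,
    cca_fit,
    crossval_cca,
    permutation_null_cca,
    reduce_dimensionality,
)


def _behavior_frame(rng, n, miss=0.0):
    sev = rng.standard_normal(n)
    load = np.array([1, 0.8, 0.7, 0.6, 0.6, -0.8, -0.5])
    vals = sev[:, None] * load[None, :] + 0.5 * rng.standard_normal((n, 7))
    df = pd.DataFrame(vals, columns=list(BEHAVIOR_SCALES))
    truth = df.copy()
    if miss:
        df = df.mask(rng.random(df.shape) < miss)
    return df, truth, sev


class TestImputation:
    def test_complete_table_returned_unchanged(self, rng):
        df, _, _ = _behavior_frame(rng, 30)
        out = impute_behavior_rf(df, seed=0)
        pd.testing.assert_frame_equal(out, df)

    def test_deterministic(self, rng):
        df, _, _ = _behavior_frame(rng, 60, miss=0.1)
        a = impute_behavior_rf(df, seed=5)
        b = impute_behavior_rf(df, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_observed_cells_never_altered(self, rng):
        df, _, _ = _behavior_frame(rng, 60, miss=0.15)
        out = impute_behavior_rf(df, seed=1)
        obs = ~df.isna()
        assert np.allclose(out.values[obs.values], df.values[obs.values])
        assert not out.isna().any().any()

    def test_beats_median_imputation_on_correlated_scales(self, rng):
        df, truth, _ = _behavior_frame(rng, 200, miss=0.1)
        out = impute_behavior_rf(df, seed=2)
        mask = df.isna().values
        rf_rmse = np.sqrt(np.mean((out.values[mask] - truth.values[mask]) ** 2))
        med = df.fillna(df.median())
        med_rmse = np.sqrt(np.mean((med.values[mask] - truth.values[mask]) ** 2))
        assert rf_rmse < med_rmse

    def test_fully_missing_column_rejected(self, rng):
        df, _, _ = _behavior_frame(rng, 30)
        df["IQ"] = np.nan
        with pytest.raises(ValueError, match="IQ"):
            impute_behavior_rf(df, seed=0)


class TestReduction:
    def test_score_variances_equal_covariance_eigenvalues(self, rng):
        x = rng.standard_normal((60, 20))
        red = reduce_dimensionality(x, k=5)
        eig = np.sort(np.linalg.eigvalsh(np.cov(x.T)))[::-1][:5]
        score_var = red.scores.var(axis=0, ddof=1)
        assert np.allclose(score_var, eig, rtol=1e-8)

    def test_full_reconstruction(self, rng):
        x = rng.standard_normal((20, 8))
        red = reduce_dimensionality(x, k=19)
        recon = red.scores @ red.basis.T
        assert np.allclose(recon, x - red.mean, atol=1e-8)

    def test_rank_deficient_input_has_no_spurious_variance(self, rng):
        base = rng.standard_normal((30, 2))
        x = base @ rng.standard_normal((2, 15))
        red = reduce_dimensionality(x, k=6)
        assert np.all(red.explained_variance[2:] < 1e-12)

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError):
            reduce_dimensionality(rng.standard_normal((5, 10)), k=5)


class TestCcaFit:
    def test_identical_sets_give_unit_correlations(self, rng):
        x = rng.standard_normal((100, 7))
        fit = cca_fit(x, x.copy())
        assert np.allclose(fit.corrs, 1.0, atol=1e-8)

    def test_null_first_correlation_small(self, rng):
        fit = cca_fit(rng.standard_normal((1000, 2)),
                      rng.standard_normal((1000, 2)))
        assert fit.corrs[0] < 0.15

    def test_invariance_to_invertible_mixing(self, rng):
        x = rng.standard_normal((200, 4))
        y = x[:, :3] @ rng.standard_normal((3, 5)) + \
            0.5 * rng.standard_normal((200, 5))
        a = rng.standard_normal((5, 5)) + 2 * np.eye(5)
        f1 = cca_fit(x, y)
        f2 = cca_fit(x, y @ a)
        assert np.allclose(f1.corrs, f2.corrs, atol=1e-8)

    def test_agrees_with_sklearn(self, rng):
        """First canonical correlation matches the independent
        scikit-learn implementation."""
        from sklearn.cross_decomposition import CCA as SkCCA
        x = rng.standard_normal((150, 5))
        y = x[:, :2] @ rng.standard_normal((2, 4)) + \
            rng.standard_normal((150, 4))
        fit = cca_fit(x, y)
        sk = SkCCA(n_components=1, max_iter=2000, tol=1e-10).fit(x, y)
        u, v = sk.transform(x, y)
        r_sk = abs(np.corrcoef(u[:, 0], v[:, 0])[0, 1])
        assert fit.corrs[0] == pytest.approx(r_sk, abs=1e-6)

    def test_sign_convention(self, rng):
        x = rng.standard_normal((100, 4))
        y = rng.standard_normal((100, 3))
        fit = cca_fit(x, y)
        assert np.all(fit.y_weights[0] >= 0)

    def test_ill_posed_size_rejected(self, rng):
        with pytest.raises(ValueError):
            cca_fit(rng.standard_normal((10, 6)), rng.standard_normal((10, 5)))


class TestLoadingsAndBackprojection:
    def test_variable_equal_to_variate_loads_one(self, rng):
        x = rng.standard_normal((200, 3))
        y = np.column_stack([x[:, 0] + 0.01 * rng.standard_normal(200),
                             rng.standard_normal(200)])
        fit = cca_fit(x, y)
        bx, by = canonical_loadings(fit, x, y)
        assert abs(by[0]) > 0.99

    def test_orthonormal_weight_axis_loadings(self, rng):
        x = rng.standard_normal((500, 3))
        y = np.column_stack([x[:, 0], rng.standard_normal(500)])
        fit = cca_fit(x, y)
        bx, _ = canonical_loadings(fit, x, y)
        # variate ~ x[:,0]; loadings approximate (1, 0, 0)
        assert abs(bx[0]) > 0.99
        assert np.all(np.abs(bx[1:]) < 0.15)

    def test_backprojection_matches_direct_multiply(self, rng):
        x = rng.standard_normal((50, 200))
        red = reduce_dimensionality(x, k=6)
        y = rng.standard_normal((50, 4))
        fit = cca_fit(red.scores, y)
        ew = backproject_brain_weights(fit, red)
        assert np.allclose(ew, red.basis @ fit.x_weights[:, 0], atol=1e-10)
        # orthonormal basis preserves the weight-vector norm
        assert np.linalg.norm(ew) == pytest.approx(
            np.linalg.norm(fit.x_weights[:, 0]), abs=1e-8)

    def test_zero_variance_variable_rejected(self, rng):
        x = rng.standard_normal((100, 3))
        y = rng.standard_normal((100, 2))
        fit = cca_fit(x, y)
        y2 = y.copy()
        y2[:, 1] = 1.0
        with pytest.raises(ValueError):
            canonical_loadings(fit, x, y2)


class TestCrossvalCCA:
    def test_noise_free_latent_gives_high_test_correlation(self, rng):
        n, e = 60, 100
        sev = rng.standard_normal(n)
        brain = np.outer(sev, rng.standard_normal(e))
        brain += 1e-3 * rng.standard_normal((n, e))
        behavior = np.outer(sev, np.ones(7)) + 1e-3 * rng.standard_normal((n, 7))
        test, _ = crossval_cca(brain, behavior, k=3, n_splits=10, k_folds=5,
                               seed=0)
        assert test.mean() > 0.95

    def test_deterministic_for_fixed_seed(self, rng):
        brain = rng.standard_normal((40, 60))
        behavior = rng.standard_normal((40, 7))
        a, sa = crossval_cca(brain, behavior, k=4, n_splits=5, k_folds=4, seed=2)
        b, sb = crossval_cca(brain, behavior, k=4, n_splits=5, k_folds=4, seed=2)
        assert np.array_equal(a, b) and np.array_equal(sa, sb)

    def test_zero_splits_rejected(self, rng):
        with pytest.raises(ValueError):
            crossval_cca(rng.standard_normal((40, 10)),
                         rng.standard_normal((40, 7)), n_splits=0)

    def test_training_folds_unaffected_by_held_out_rows(self, rng):
        """Leakage check: corrupting a held-out subject's data does not
        change the training-fold reduction or weights for that fold."""
        from taskpotency.cca import _fold_assignment, reduce_dimensionality, cca_fit
        n, e = 40, 60
        brain = rng.standard_normal((n, e))
        behavior = rng.standard_normal((n, 7))
        assign = _fold_assignment(n, 4, np.random.default_rng(0))
        test_rows = np.flatnonzero(assign == 0)
        train = assign != 0
        red1 = reduce_dimensionality(brain[train], 4)
        fit1 = cca_fit(red1.scores, behavior[train])
        corrupted = brain.copy()
        corrupted[test_rows] += 100.0
        red2 = reduce_dimensionality(corrupted[train], 4)
        fit2 = cca_fit(red2.scores, behavior[train])
        assert np.array_equal(red1.basis, red2.basis)
        assert np.array_equal(fit1.x_weights, fit2.x_weights)


class TestPermutationNull:
    def test_within_site_multiset_preserved(self, rng):
        """Permutation only reorders behavior rows within each site."""
        n = 30
        brain = rng.standard_normal((n, 40))
        behavior = rng.standard_normal((n, 7))
        site = np.array(["a", "b", "c"])[np.arange(n) % 3]

        seen = {}
        import taskpotency.cca as cca_mod
        orig = cca_mod._oos_pass

        def spy(brain_, behavior_, *args, **kwargs):
            seen["behavior"] = behavior_.copy()
            return orig(brain_, behavior_, *args, **kwargs)

        cca_mod._oos_pass = spy
        try:
            permutation_null_cca(brain, behavior, site, k=4,
                                 n_permutations=1, k_folds=3, seed=1)
        finally:
            cca_mod._oos_pass = orig
        for lab in "abc":
            rows = site == lab
            a = np.sort(seen["behavior"][rows], axis=0)
            b = np.sort(behavior[rows], axis=0)
            assert np.allclose(a, b)

    def test_deterministic(self, rng):
        brain = rng.standard_normal((30, 40))
        behavior = rng.standard_normal((30, 7))
        site = np.zeros(30, dtype=int)
        a = permutation_null_cca(brain, behavior, site, k=4, n_permutations=4,
                                 k_folds=3, seed=9)
        b = permutation_null_cca(brain, behavior, site, k=4, n_permutations=4,
                                 k_folds=3, seed=9)
        assert np.array_equal(a, b)

    def test_null_overlaps_test_for_independent_data(self, rng):
        brain = rng.standard_normal((60, 80))
        behavior = rng.standard_normal((60, 7))
        site = np.array(["a", "b"])[np.arange(60) % 2]
        test, _ = crossval_cca(brain, behavior, k=5, n_splits=20, k_folds=5,
                               seed=0)
        null = permutation_null_cca(brain, behavior, site, k=5,
                                    n_permutations=20, k_folds=5, seed=1)
        t_lo, t_hi = np.percentile(test, [25, 75])
        n_lo, n_hi = np.percentile(null, [25, 75])
        assert max(t_lo, n_lo) <= min(t_hi, n_hi)


class TestSignificance:
    def test_clear_separation_significant(self):
        d = assess_significance(np.full(10, 0.9), np.linspace(0, 0.3, 100))
        assert d.significant

    def test_weak_test_not_significant(self):
        d = assess_significance(np.full(10, 0.2),
                                np.linspace(0, 0.5, 100))
        assert not d.significant

    def test_identical_distributions_not_significant(self, rng):
        x = rng.standard_normal(200)
        assert not assess_significance(x, x).significant

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            assess_significance([], [0.1])


class TestModelObject:
    def test_fit_returns_complete_results(self, rng):
        n, e = 50, 80
        sev = rng.standard_normal(n)
        brain = rng.standard_normal((n, e))
        brain[:, :10] += sev[:, None]
        df, _, _ = _behavior_frame(rng, n)
        df.iloc[:] = (sev[:, None] *
                      np.array([1, .8, .7, .6, .6, -.8, -.5])[None, :]
                      + 0.7 * rng.standard_normal((n, 7)))
        model = BrainBehaviorCCA(brain, df, k=5, n_splits=8, k_folds=5,
                                 n_permutations=8, task="demo")
        res = model.fit(seed=0)
        assert res.test_dist.shape == (8,)
        assert res.null_dist.shape == (8,)
        assert res.behavior_weights[0] >= 0  # SRS sign convention
        assert res.edge_weights.shape == (e,)
        s = res.summary()
        assert "SRS" in s and "demo" in s

    def test_missing_behavior_rejected(self, rng):
        df, _, _ = _behavior_frame(rng, 40, miss=0.2)
        with pytest.raises(ValueError, match="impute"):
            BrainBehaviorCCA(rng.standard_normal((40, 20)), df)
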