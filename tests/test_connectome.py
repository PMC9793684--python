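"""Connectivity primitives: shrinkage covariance, partial correlation,
Fisher-Z, the Gaussian-gamma edge mixture, normalization and task potency."""

import numpy as np
import pytest

from taskpotency.connectome import (
    ConnectivityMatrix,
    EdgeTable,
    MixtureFit,
    fisher_z,
    fit_edge_mixture,
    normalize_connectivity,
    partial_correlation,
    shrinkage_covariance,
    task_potency,
    unvectorize_edges,
    vectorize_edges,
    PotencyMatrix,
)


class TestShrinkageCovariance:
    def test_recovers_identity_at_large_t(self, rng):
        x = rng.standard_normal((10_000, 5))
        cov, shrink = shrinkage_covariance(x)
        assert np.linalg.norm(cov - np.eye(5), "fro") < 0.05
        assert 0.0 <= shrink <= 1.0

    def test_output_positive_definite(self, rng):
        x = rng.standard_normal((40, 30))  # more regions than df would allow raw
        cov, _ = shrinkage_covariance(x)
        assert np.linalg.eigvalsh(cov).min() > 0

    def test_constant_column_rejected(self, rng):
        x = rng.standard_normal((100, 4))
        x[:, 2] = 1.0
        with pytest.raises(ValueError, match="column 2"):
            shrinkage_covariance(x)

    def test_too_few_timepoints_rejected(self, rng):
        with pytest.raises(ValueError, match="timepoints"):
            shrinkage_covariance(rng.standard_normal((10, 4)))


class TestPartialCorrelation:
    def test_identity_gives_zero_off_diagonal(self):
        assert np.allclose(partial_correlation(np.eye(4)), 0.0)

    def test_two_variables_equal_marginal_correlation(self):
        r = 0.37
        cov = np.array([[1.0, r], [r, 1.0]])
        p = partial_correlation(cov)
        assert p[0, 1] == pytest.approx(r, abs=1e-12)

    @pytest.mark.parametrize("dim", [4, 5, 6, 7, 8])
    def test_matches_residual_regression_oracle(self, dim, rng):
        """Partial correlation equals the correlation of the residuals of each
        pair after regressing out all remaining variables."""
        a = rng.standard_normal((dim, dim))
        cov = a @ a.T + dim * np.eye(dim)
        x = np.linalg.cholesky(cov)
        z = rng.standard_normal((5_000, dim)) @ x.T
        p_sample = partial_correlation(np.cov(z.T))
        for i in range(dim):
            for j in range(i + 1, dim):
                others = [k for k in range(dim) if k not in (i, j)]
                q = np.column_stack([z[:, others], np.ones(len(z))])
                proj = q @ np.linalg.lstsq(q, z[:, [i, j]], rcond=None)[0]
                resid = z[:, [i, j]] - proj
                r_oracle = np.corrcoef(resid.T)[0, 1]
                assert p_sample[i, j] == pytest.approx(r_oracle, abs=1e-8)
        assert np.all(np.abs(p_sample) <= 1)

    def test_singular_covariance_rejected(self):
        cov = np.ones((3, 3))
        with pytest.raises(ValueError):
            partial_correlation(cov)


class TestFisherZ:
    def test_closed_form_values(self):
        m = np.array([[0.0, 0.5], [0.5, 0.0]])
        z = fisher_z(m)
        assert z[0, 1] == pytest.approx(0.5493, abs=1e-4)
        assert fisher_z(np.zeros((3, 3)))[0, 1] == 0.0

    def test_odd_symmetry(self):
        r = np.array([[0.0, 0.3], [0.3, 0.0]])
        assert np.allclose(fisher_z(-r), -fisher_z(r))

    def test_diagonal_stays_zero(self):
        m = 0.9 * np.ones((3, 3))
        np.fill_diagonal(m, 1.0)  # would be arctanh(1) without special-casing
        assert np.allclose(np.diag(fisher_z(m)), 0.0)

    def test_unit_correlation_rejected(self):
        m = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError):
            fisher_z(m)


class TestEdgeMixture:
    def test_recovers_pure_gaussian(self):
        rng = np.random.default_rng(0)
        fit = fit_edge_mixture(rng.normal(2.0, 3.0, 14028))
        assert fit.mean_gauss == pytest.approx(2.0, abs=0.1)
        assert fit.sd_gauss == pytest.approx(3.0, abs=0.15)
        assert fit.weight_pos < 0.05 and fit.weight_neg < 0.05

    def test_recovers_three_component_weights(self):
        rng = np.random.default_rng(100)
        n = 14028
        comp = rng.choice(3, n, p=[0.8, 0.1, 0.1])
        x = np.where(comp == 0, rng.normal(0, 1, n),
                     np.where(comp == 1, rng.gamma(3, 1, n),
                              -rng.gamma(3, 1, n)))
        fit = fit_edge_mixture(x)
        assert fit.weight_gauss == pytest.approx(0.8, abs=0.05)
        assert fit.weight_pos == pytest.approx(0.1, abs=0.05)
        assert fit.weight_neg == pytest.approx(0.1, abs=0.05)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(3)
        fit = fit_edge_mixture(rng.normal(0, 1, 2000))
        assert fit.weight_gauss + fit.weight_pos + fit.weight_neg == \
            pytest.approx(1.0, abs=1e-8)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            fit_edge_mixture(np.ones(1000))

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            fit_edge_mixture(np.random.default_rng(0).normal(size=100))


def _random_fisher_matrix(rng, r=12):
    v = 0.3 * rng.standard_normal((r, r))
    v = 0.5 * (v + v.T)
    np.fill_diagonal(v, 0.0)
    return v


class TestNormalization:
    def test_identity_fit_is_identity_map(self, rng):
        m = ConnectivityMatrix("s", "rest", _random_fisher_matrix(rng))
        fit = MixtureFit(1, 0, 1, 0, 1, 1, 0, 1, 1, 0.0, True)
        out = normalize_connectivity(m, fit)
        assert np.allclose(out.values, m.values)
        assert out.state == "normalized"

    def test_affine_map(self, rng):
        v = _random_fisher_matrix(rng)
        v[0, 1] = v[1, 0] = 8.0
        m = ConnectivityMatrix("s", "rest", v)
        fit = MixtureFit(1, 2, 3, 0, 1, 1, 0, 1, 1, 0.0, True)
        assert normalize_connectivity(m, fit).values[0, 1] == pytest.approx(2.0)

    def test_self_consistency_after_normalization(self):
        """Refitting the mixture on normalized edges gives mu ~ 0, sd ~ 1."""
        rng = np.random.default_rng(1)
        r = 60
        v = fisher_z(np.clip(0.3 + 0.2 * rng.standard_normal((r, r)), -0.99, 0.99))
        v = 0.5 * (v + v.T)
        np.fill_diagonal(v, 0.0)
        m = ConnectivityMatrix("s", "rest", v)
        iu, ju = np.triu_indices(r, k=1)
        fit = fit_edge_mixture(m.values[iu, ju])
        out = normalize_connectivity(m, fit)
        refit = fit_edge_mixture(out.values[iu, ju])
        assert refit.mean_gauss == pytest.approx(0.0, abs=0.05)
        assert refit.sd_gauss == pytest.approx(1.0, abs=0.05)

    def test_shift_equivariance(self):
        """A constant shift of every raw edge is absorbed by the location fit."""
        rng = np.random.default_rng(2)
        r = 60
        v = 0.3 * rng.standard_normal((r, r))
        v = 0.5 * (v + v.T)
        np.fill_diagonal(v, 0.0)
        iu, ju = np.triu_indices(r, k=1)
        m1 = ConnectivityMatrix("s", "rest", v)
        shifted = v + 5.0
        np.fill_diagonal(shifted, 0.0)
        m2 = ConnectivityMatrix("s", "rest", shifted)
        out1 = normalize_connectivity(m1, fit_edge_mixture(m1.values[iu, ju]))
        out2 = normalize_connectivity(m2, fit_edge_mixture(m2.values[iu, ju]))
        assert np.max(np.abs(out1.values[iu, ju] - out2.values[iu, ju])) < 0.02

    def test_requires_raw_state(self, rng):
        m = ConnectivityMatrix("s", "rest", _random_fisher_matrix(rng),
                               state="normalized")
        fit = MixtureFit(1, 0, 1, 0, 1, 1, 0, 1, 1, 0.0, True)
        with pytest.raises(ValueError):
            normalize_connectivity(m, fit)


class TestTaskPotency:
    def _norm(self, rng, sid="s", cond="hariri"):
        return ConnectivityMatrix(sid, cond, _random_fisher_matrix(rng),
                                  state="normalized")

    def test_identical_inputs_give_zero(self, rng):
        m = self._norm(rng)
        rest = ConnectivityMatrix("s", "rest", m.values, state="normalized")
        assert np.allclose(task_potency(m, rest).values, 0.0)

    def test_antisymmetry(self, rng):
        a, b = self._norm(rng), self._norm(rng, cond="rest")
        assert np.allclose(task_potency(a, b).values, -task_potency(b, a).values)

    def test_elementwise_difference(self):
        t = np.array([[0.0, 1.5], [1.5, 0.0]])
        r = np.array([[0.0, 0.5], [0.5, 0.0]])
        a = ConnectivityMatrix("s", "t", t, state="normalized")
        b = ConnectivityMatrix("s", "rest", r, state="normalized")
        assert task_potency(a, b).values[0, 1] == pytest.approx(1.0)

    def test_subject_and_state_guards(self, rng):
        a = self._norm(rng, sid="s1")
        b = self._norm(rng, sid="s2", cond="rest")
        with pytest.raises(ValueError, match="subject"):
            task_potency(a, b)
        raw = ConnectivityMatrix("s1", "rest", _random_fisher_matrix(rng))
        with pytest.raises(ValueError, match="normalized"):
            task_potency(a, raw)


class TestEdgeVectorization:
    def test_ordering_convention(self, rng):
        mats = [PotencyMatrix("s0", "t", _random_fisher_matrix(rng, 4))]
        tab = vectorize_edges(mats, task="t")
        assert tab.n_edges == 6
        assert tab.edge_index[:2] == [(0, 1), (0, 2)]

    def test_edge_count_at_full_scale(self):
        r = 168
        iu, _ = np.triu_indices(r, k=1)
        assert iu.size == 14028

    def test_round_trip_identity(self, rng):
        v = _random_fisher_matrix(rng, 9)
        tab = vectorize_edges([PotencyMatrix("s", "t", v)], task="t")
        assert np.array_equal(unvectorize_edges(tab.values[0], 9), v)

    def test_tsv_round_trip(self, rng, tmp_path):
        mats = [PotencyMatrix(f"s{i}", "t", _random_fisher_matrix(rng, 5))
                for i in range(3)]
        tab = vectorize_edges(mats, task="t")
        tab.to_tsv(tmp_path / "e.tsv")
        back = EdgeTable.from_tsv(tmp_path / "e.tsv", "t")
        assert back.subject_ids == tab.subject_ids
        assert back.edge_index == tab.edge_index
        assert np.allclose(back.values, tab.values)

    def test_shape_mismatch_rejected(self, rng):
        mats = [PotencyMatrix("a", "t", _random_fisher_matrix(rng, 5)),
                PotencyMatrix("b", "t", _random_fisher_matrix(rng, 6))]
        with pytest.raises(ValueError):
            vectorize_edges(mats, task="t")
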