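import numpy as np
import pytest

from sparsesca import (
    BlockSpec,
    MultiBlockMatrix,
    PenaltyConfig,
    SolverOptions,
    fit_sparse_loadings,
    fit_sparse_weights,
    loss_loadings,
    loss_weights,
    ordinary_sca,
    preprocess,
    variance_accounted,
    zero_pattern,
)
from sparsesca._solver import (
    update_loadings,
    update_orthogonal_P,
    update_orthogonal_T,
    update_weights,
)
from sparsesca.penalties import penalty_value

from conftest import make_correlated_data, make_data


def random_orthonormal(rng, n, r, count):
    """Batch of random column-orthonormal matrices."""
    return np.linalg.qr(rng.normal(size=(count, n, r)))[0]


class TestOrdinarySCA:
    def test_full_rank_fit_is_one(self):
        data = make_data(0, 10, (3, 2))
        *_, fit, _ = ordinary_sca(data, 5)
        assert np.isclose(fit, 1.0)

    def test_fit_matches_eigendecomposition_oracle(self):
        data = make_data(1, 10, (4, 2))
        # independent route: eigenvalues of the Gram matrix
        evals = np.sort(np.linalg.eigvalsh(data.values.T @ data.values))[::-1]
        expected = evals[:2].sum() / evals.sum()
        *_, fit, _ = ordinary_sca(data, 2)
        assert np.isclose(fit, expected, atol=1e-10)

    def test_scores_orthogonal(self):
        data = make_data(2, 12, (5,))
        _, _, T, _, _ = ordinary_sca(data, 3)
        off = T.T @ T - np.diag(np.diag(T.T @ T))
        assert np.abs(off).max() < 1e-10

    def test_r_out_of_range(self):
        data = make_data(3, 6, (4,))
        with pytest.raises(ValueError):
            ordinary_sca(data, 7)


class TestProcrustesUpdates:
    def test_diagonal_M_gives_identity_columns(self):
        # build X, W so that W'X'X = [diag(2,3) | 0]
        M = np.hstack([np.diag([2.0, 3.0]), np.zeros((2, 2))])
        # direct check of the polar factor on M itself
        U, _, Vt = np.linalg.svd(M, full_matrices=False)
        P = Vt.T @ U.T
        np.testing.assert_allclose(P, np.eye(4)[:, :2], atol=1e-12)

    def test_P_update_beats_random_candidates(self, rng):
        data = make_data(4, 8, (3, 2))
        W = rng.normal(size=(5, 2))
        P = update_orthogonal_P(data, W)
        M = W.T @ data.values.T @ data.values
        best = np.trace(M @ P)
        Q = random_orthonormal(rng, 5, 2, 10_000)
        competitors = np.einsum("rj,njr->n", M, Q)
        assert best >= competitors.max() - 1e-10

    def test_T_update_beats_random_candidates(self, rng):
        data = make_data(5, 7, (4,))
        Pmat = rng.normal(size=(4, 2))
        T = update_orthogonal_T(data, Pmat)
        assert np.abs(T.T @ T - np.eye(2)).max() < 1e-10
        M = Pmat.T @ data.values.T
        best = np.trace(M @ T)
        Q = random_orthonormal(rng, 7, 2, 10_000)
        competitors = np.einsum("ri,nir->n", M, Q)
        assert best >= competitors.max() - 1e-10

    def test_T_update_recovers_exact_decomposition(self, rng):
        T0 = np.linalg.qr(rng.normal(size=(8, 2)))[0]
        P0 = rng.normal(size=(5, 2)) @ np.diag([3.0, 1.5])
        X = T0 @ P0.T
        T = update_orthogonal_T(X, P0)
        C = np.abs(T.T @ T0)
        np.testing.assert_allclose(C, np.eye(2), atol=1e-8)

    def test_unpenalized_P_spans_weight_space(self):
        data = make_data(6, 15, (3, 3))
        W, *_ = ordinary_sca(data, 2)
        P = update_orthogonal_P(data, W)
        # principal angles between the two column spaces
        Qw = np.linalg.qr(W)[0]
        Qp = np.linalg.qr(P)[0]
        s = np.linalg.svd(Qw.T @ Qp, compute_uv=False)
        assert np.all(s > 1 - 1e-8)


class TestMMUpdates:
    def test_unpenalized_full_rank_returns_P(self, rng):
        data = make_data(7, 12, (3, 2))
        P = np.linalg.qr(rng.normal(size=(5, 2)))[0]
        W = update_weights(data, P, P.copy(), PenaltyConfig())
        np.testing.assert_allclose(W, P, atol=1e-9)

    def test_ridge_closed_form(self, rng):
        data = make_data(8, 12, (4,))
        G = data.values.T @ data.values
        P = np.linalg.qr(rng.normal(size=(4, 2)))[0]
        cfg = PenaltyConfig(lambda_ridge=0.8)
        W = update_weights(data, P, P.copy(), cfg)
        expected = np.linalg.solve(0.8 * np.eye(4) + G, G @ P)
        np.testing.assert_allclose(W, expected, atol=1e-10)

    def test_woodbury_agrees_with_direct(self, rng):
        data = make_data(9, 5, (20, 10))
        P = np.linalg.qr(rng.normal(size=(30, 2)))[0]
        W0 = rng.normal(size=(30, 2))
        cfg = PenaltyConfig(lambda_lasso=0.3, lambda_ridge=0.2)
        direct = update_weights(data, P, W0, cfg, use_woodbury="off")
        wood = update_weights(data, P, W0, cfg, use_woodbury="on")
        assert np.abs(direct - wood).max() < 1e-10

    def test_unpenalized_underdetermined_suggests_ridge(self, rng):
        data = make_data(10, 5, (8,))
        P = np.linalg.qr(rng.normal(size=(8, 2)))[0]
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            update_weights(data, P, P.copy(), PenaltyConfig())

    def test_surrogate_stationarity(self, rng):
        """The weights update zeroes the gradient of the MM surrogate."""
        from sparsesca.penalties import majorizer_diagonal

        data = make_data(11, 10, (3, 3))
        G = data.values.T @ data.values
        P = np.linalg.qr(rng.normal(size=(6, 2)))[0]
        W0 = rng.normal(size=(6, 2))
        cfg = PenaltyConfig(lambda_lasso=0.4, lambda_group=0.3, lambda_ridge=0.1)
        W = update_weights(data, P, W0, cfg)
        D = majorizer_diagonal(W0, cfg, data.blocks)
        grad = 2 * (G @ W - G @ P) + 2 * D * W
        assert np.abs(grad).max() < 1e-6

    def test_loadings_unpenalized_and_ridge_forms(self, rng):
        data = make_data(12, 9, (4,))
        T = np.linalg.qr(rng.normal(size=(9, 2)))[0]
        P0 = rng.normal(size=(4, 2))
        P = update_loadings(data, T, P0, PenaltyConfig())
        np.testing.assert_allclose(P, data.values.T @ T, atol=1e-12)
        P = update_loadings(data, T, P0, PenaltyConfig(lambda_ridge=1.0))
        np.testing.assert_allclose(P, data.values.T @ T / 2.0, atol=1e-12)


class TestLosses:
    def test_zero_model_loss_is_total_ss(self):
        data = make_data(13, 10, (3, 2))
        Z = np.zeros((5, 2))
        cfg = PenaltyConfig(lambda_lasso=1.0, lambda_ridge=2.0)
        assert np.isclose(loss_weights(data, Z, Z, cfg), 5.0)  # preprocessed
        T = np.zeros((10, 2))
        assert np.isclose(loss_loadings(data, T, Z, cfg), 5.0)

    def test_exact_unpenalized_model_loss_zero(self, rng):
        T0 = np.linalg.qr(rng.normal(size=(8, 2)))[0]
        P0 = rng.normal(size=(5, 2))
        X = T0 @ P0.T
        assert loss_loadings(X, T0, P0, PenaltyConfig()) < 1e-20

    def test_random_configuration_matches_recomputation(self, rng):
        data = make_data(14, 9, (3, 2))
        W = rng.normal(size=(5, 2))
        P = rng.normal(size=(5, 2))
        cfg = PenaltyConfig(
            lambda_lasso=0.3, lambda_ridge=0.2, lambda_group=0.1, group_size_scaling=True
        )
        resid = data.values - data.values @ W @ P.T
        expected = (resid**2).sum() + penalty_value(W, cfg, data.blocks)
        assert np.isclose(loss_weights(data, W, P, cfg), expected, atol=1e-10)


PRESET_CONFIGS = [
    PenaltyConfig(),
    PenaltyConfig(lambda_lasso=0.4),
    PenaltyConfig(lambda_lasso=0.4, lambda_ridge=0.2),
    PenaltyConfig(lambda_group=0.5),
    PenaltyConfig(lambda_lasso=0.3, lambda_group=0.4),
    PenaltyConfig(lambda_elitist=0.4),
    PenaltyConfig(lambda_elitist=0.4, lambda_ridge=0.2),
]


class TestFullFits:
    @pytest.mark.parametrize("model", ["weights", "loadings"])
    def test_unpenalized_reduces_to_svd(self, model):
        data = make_data(15, 20, (4, 3))
        *_, fit_svd, _ = ordinary_sca(data, 2)
        fitter = fit_sparse_weights if model == "weights" else fit_sparse_loadings
        _, _, report = fitter(data, PenaltyConfig(), 2)
        assert abs(report.fit - fit_svd) < 1e-8

    @pytest.mark.parametrize("cfg", PRESET_CONFIGS)
    @pytest.mark.parametrize("model", ["weights", "loadings"])
    def test_monotone_loss(self, cfg, model):
        data = make_correlated_data(16, 15, (5, 4))
        fitter = fit_sparse_weights if model == "weights" else fit_sparse_loadings
        _, _, report = fitter(data, cfg, 2, SolverOptions(max_iter=300))
        losses = report.loss_per_iteration
        assert np.all(np.diff(losses) <= 1e-9 * np.abs(losses[:-1]))

    def test_lasso_cardinality_bound(self):
        """Lasso-only weights with more variables than samples keep at
        most I non-zero weights per component."""
        data = make_correlated_data(17, 8, (10, 6))
        cfg = PenaltyConfig(lambda_lasso=0.05)
        W, _, report = fit_sparse_weights(
            data, cfg, 2, SolverOptions(max_iter=3000, tol=1e-12)
        )
        nonzeros = (np.abs(W) > 0).sum(axis=0)
        assert np.all(nonzeros <= data.n_samples)

    def test_loadings_multistart_agreement_unpenalized(self):
        """With more variables than samples and no ridge, the loadings
        model's solution is unique: random starts reach the same loss."""
        for seed in range(3):
            data = make_data(50 + seed, 10, (15, 10))
            _, _, report = fit_sparse_loadings(
                data, PenaltyConfig(), 3,
                SolverOptions(n_starts=5, seed=seed, tol=1e-13),
            )
            spread = report.start_losses.max() - report.start_losses.min()
            assert spread < 1e-6

    def test_sparse_pca_special_case_blocks_irrelevant(self):
        """One block with lasso+ridge (sparse PCA) gives the same result
        as the same data under an arbitrary partition."""
        rng = np.random.default_rng(18)
        X = rng.normal(size=(12, 6))
        cfg = PenaltyConfig(lambda_lasso=0.3, lambda_ridge=0.2)
        opts = SolverOptions()
        one = preprocess(MultiBlockMatrix(X, BlockSpec.from_sizes([6])))
        two = preprocess(MultiBlockMatrix(X, BlockSpec.from_sizes([4, 2])))
        W1, P1, _ = fit_sparse_weights(one, cfg, 2, opts)
        W2, P2, _ = fit_sparse_weights(two, cfg, 2, opts, blocks=two.blocks)
        np.testing.assert_allclose(W1, W2, atol=1e-10)
        np.testing.assert_allclose(P1, P2, atol=1e-10)

    def test_zero_loading_reconstructs_zero_variable(self, rng):
        """In the score-based model a zero loading forces the
        reconstructed variable to the zero vector."""
        T = np.linalg.qr(rng.normal(size=(9, 1)))[0]
        P = rng.normal(size=(4, 1))
        P[2, 0] = 0.0
        recon = T @ P.T
        assert np.all(recon[:, 2] == 0)
        assert np.any(recon[:, 0] != 0)

    def test_component_ordering_and_sign_convention(self):
        data = make_correlated_data(19, 15, (5, 4))
        W, P, _ = fit_sparse_weights(
            data, PenaltyConfig(lambda_lasso=0.1, lambda_ridge=0.1), 3
        )
        ev = ((data.values @ W) ** 2).sum(axis=0)
        assert np.all(np.diff(ev) <= 1e-10)
        for r in range(W.shape[1]):
            col = W[:, r]
            if col.any():
                assert col[np.argmax(np.abs(col))] > 0


class TestSummaries:
    def test_variance_accounted_extremes(self, rng):
        data = make_data(20, 10, (3, 2))
        W, P, *_ = ordinary_sca(data, 5)
        fit, clipped = variance_accounted(data, W, P=P)
        assert np.isclose(fit, 1.0) and not clipped
        Z = np.zeros((5, 2))
        fit, _ = variance_accounted(data, Z, P=Z)
        assert fit == 0.0

    def test_variance_accounted_matches_direct(self, rng):
        data = make_data(21, 9, (4,))
        W = rng.normal(size=(4, 2))
        P = rng.normal(size=(4, 2))
        fit, _ = variance_accounted(data, W, P=P)
        resid = data.values - data.values @ W @ P.T
        assert np.isclose(fit, 1 - (resid**2).sum() / (data.values**2).sum())

    def test_zero_pattern_counts(self):
        spec = BlockSpec.from_sizes([2, 2])
        C = np.array([[0.0, 1.0], [0.0, 0.0], [2.0, 0.0], [0.5, 1e-12]])
        zs = zero_pattern(C, 1e-8, spec)
        assert zs.overall_pct == 62.5
        np.testing.assert_array_equal(zs.per_component_counts, [2, 3])
        assert np.all(zero_pattern(np.zeros((3, 2)), 0.0, BlockSpec.from_sizes([3])).pattern)
        assert zero_pattern(np.ones((3, 1)), 1e-8, BlockSpec.from_sizes([3])).overall_pct == 0.0
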