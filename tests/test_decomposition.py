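import numpy as np
import pytest

from latnet.decomposition import (
    RPCAConfig, adaptive_rpca, dematricize, decompose_weights, matricize,
    objective, split_components,
)


@pytest.fixture
def pcp_cfg():
    """Solver settings for generic unit-scale matrices (standard PCP
    regularization scale 1/sqrt(max dim), sharp column adaptation)."""
    return RPCAConfig(beta=1 / np.sqrt(300), gamma=0.3)


class TestMatricize:
    def test_default_tensor_shape(self, contour_weights):
        M = matricize(contour_weights)
        assert M.shape == (18, 18 * 43 * 43) == (18, 33282)

    def test_round_trip_identity(self):
        T = np.random.default_rng(0).random((4, 4, 5, 5))
        assert np.array_equal(dematricize(matricize(T), T.shape), T)

    def test_rank_bounded_by_rows(self, contour_weights):
        M = matricize(contour_weights)
        assert np.linalg.matrix_rank(M) <= 18


class TestAdaptiveRPCA:
    def test_zero_matrix(self):
        L, S, info = adaptive_rpca(np.zeros((5, 8)))
        assert np.all(L == 0) and np.all(S == 0) and info["converged"]

    def test_exact_rank_one_uncorrupted(self, pcp_cfg):
        rng = np.random.default_rng(1)
        G = np.outer(rng.random(18), rng.random(300))
        L, S, info = adaptive_rpca(G, pcp_cfg)
        assert np.linalg.norm(S) / np.linalg.norm(G) < 1e-3
        assert np.linalg.norm(L - G) / np.linalg.norm(G) < 1e-3

    def test_rank2_plus_column_sparse_recovery(self, pcp_cfg):
        rng = np.random.default_rng(1)
        A = rng.standard_normal((18, 2)) @ rng.standard_normal((2, 300))
        cols = [10, 100, 200]
        C = np.zeros((18, 300))
        C[:, cols] = rng.standard_normal((18, 3)) * np.abs(A).mean() * 3
        L, S, info = adaptive_rpca(A + C, pcp_cfg)
        nz = np.where(np.abs(S).max(axis=0) > 1e-6)[0]
        assert list(nz) == cols
        sv = np.linalg.svd(L, compute_uv=False)
        assert int((sv > 1e-6 * sv[0]).sum()) == 2
        assert info["residual"] <= pcp_cfg.tol

    def test_objective_beats_trivial_feasible_points(self, pcp_cfg):
        rng = np.random.default_rng(2)
        G = (rng.standard_normal((18, 3)) @ rng.standard_normal((3, 300))
             + 0.01 * rng.standard_normal((18, 300)))
        L, S, info = adaptive_rpca(G, pcp_cfg)
        lam = info["lambda"]
        obj = objective(L, S, lam)
        assert obj <= objective(G, np.zeros_like(G), lam) + 1e-9
        assert obj <= objective(np.zeros_like(G), G, lam) + 1e-9

    def test_deterministic(self, pcp_cfg):
        G = np.random.default_rng(3).standard_normal((10, 40))
        r1 = adaptive_rpca(G, pcp_cfg)
        r2 = adaptive_rpca(G, pcp_cfg)
        assert np.array_equal(r1[0], r2[0]) and np.array_equal(r1[1], r2[1])

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            adaptive_rpca(np.array([[1.0, np.nan]]))

    def test_nonconvergence_warns(self):
        G = np.random.default_rng(4).standard_normal((10, 30))
        with pytest.warns(RuntimeWarning):
            _, _, info = adaptive_rpca(G, RPCAConfig(tol=1e-16, max_iter=3))
        assert not info["converged"]

    def test_literal_lambda_rule_runs(self):
        G = np.random.default_rng(5).standard_normal((8, 20))
        L, S, info = adaptive_rpca(G, RPCAConfig(adaptive_rule="literal"))
        assert np.allclose(L + S, G, atol=1e-5 * np.linalg.norm(G))


class TestSplitComponents:
    def test_positive_rank_one_has_no_negative_part(self):
        u, v = np.abs(np.random.default_rng(6).random(8)), \
               np.abs(np.random.default_rng(7).random(20))
        L = np.outer(u, v)
        dec = split_components(L, np.zeros_like(L), 1.0)
        assert np.all(dec.W_LR_neg == 0)
        assert np.allclose(dec.W_LR_pos, L, atol=1e-10)

    def test_signed_parts_sum_to_truncated_L(self):
        rng = np.random.default_rng(8)
        L = rng.standard_normal((10, 30))
        dec = split_components(L, np.zeros_like(L), 0.99)
        U, s, Vt = np.linalg.svd(L, full_matrices=False)
        r = dec.retained_rank
        L_trunc = (U[:, :r] * s[:r]) @ Vt[:r]
        assert np.allclose(dec.W_LR_pos + dec.W_LR_neg, L_trunc, atol=1e-10)
        assert np.all(dec.W_LR_pos >= 0) and np.all(dec.W_LR_neg <= 0)

    def test_sparse_split_reassembles(self):
        S = np.random.default_rng(9).standard_normal((6, 12))
        dec = split_components(np.zeros_like(S), S, 0.99)
        assert np.array_equal(dec.W_S_pos + dec.W_S_neg, S)

    def test_variance_truncation_rank(self):
        # singular values 3, 1: rank 1 keeps 9/10 of variance
        L = np.diag([3.0, 1.0]) @ np.eye(2, 10)
        dec = split_components(L, np.zeros_like(L), 0.9)
        assert dec.retained_rank == 1
        dec2 = split_components(L, np.zeros_like(L), 0.95)
        assert dec2.retained_rank == 2


class TestEndToEnd:
    def test_decompose_learned_tensor(self, contour_weights):
        dec = decompose_weights(contour_weights)
        assert dec.converged
        assert dec.residual <= 1e-7
        assert 0 < dec.retained_rank <= 18
        G = matricize(contour_weights)
        dec.validate(G=G, tol=1e-6)
        assert 0.0 <= dec.sparsity_entries
        assert dec.tensor_shape == contour_weights.W.shape

    def test_config_validation(self):
        with pytest.raises(ValueError):
            RPCAConfig(beta=0)
        with pytest.raises(ValueError):
            RPCAConfig(variance_retained=1.5)
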