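import numpy as np
import pytest

from latnet.inference import (
    ContextConfig, contextual_inference_exact, contextual_inference_linear,
    surround_effect_stats, surround_term,
)


@pytest.fixture
def hand_case():
    """2 features, 2 patches, the hand-computable product-form case."""
    c = np.array([[[0.6, 0.9]], [[0.4, 0.1]]])  # (K, 1, 2)
    W = np.zeros((2, 2, 1, 3))
    for off in (0, 2):  # both neighbor directions
        W[0, 0, 0, off] = 1.0
        W[1, 1, 0, off] = 1.0
        W[0, 1, 0, off] = -1.0
        W[1, 0, 0, off] = -1.0
    return c, W


class TestExactMode:
    def test_zero_weights_identity(self):
        rng = np.random.default_rng(0)
        c = rng.random((3, 2, 4))
        c /= c.sum(axis=0)
        f = contextual_inference_exact(c, np.zeros((3, 3, 3, 3)))
        assert np.allclose(f.values, c, atol=1e-12)

    def test_hand_computed_example(self, hand_case):
        c, W = hand_case
        f = contextual_inference_exact(c, W)
        # patch 1 brackets: feature 1: 1 + 0.9 - 0.1 = 1.8 -> 0.6*1.8 = 1.08
        #                   feature 2: 1 - 0.9 + 0.1 = 0.2 -> 0.4*0.2 = 0.08
        assert f.values[0, 0, 0] == pytest.approx(1.08 / 1.16, abs=1e-12)
        assert f.values[1, 0, 0] == pytest.approx(0.08 / 1.16, abs=1e-12)

    def test_normalization_contract(self):
        rng = np.random.default_rng(1)
        c = rng.random((4, 3, 3))
        c /= c.sum(axis=0)
        W = rng.uniform(-0.3, 0.3, size=(4, 4, 3, 3))
        f = contextual_inference_exact(c, W)
        assert np.allclose(f.values.sum(axis=0), 1.0, atol=1e-12)
        assert np.all(f.values >= 0)

    def test_annihilated_patch_falls_back_to_uniform(self):
        c = np.array([[[1.0, 1.0]], [[0.0, 0.0]]])
        W = np.zeros((2, 2, 1, 3))
        W[0, 0, 0, 0] = W[0, 0, 0, 2] = -1.0  # bracket 1 - c = 0
        with pytest.warns(RuntimeWarning):
            f = contextual_inference_exact(c, W)
        assert np.allclose(f.values[:, 0, 0], 0.5)


class TestLinearMode:
    def test_alpha_zero_identity(self):
        rng = np.random.default_rng(2)
        c = rng.random((3, 5, 5))
        W = rng.standard_normal((3, 3, 3, 3))
        assert np.array_equal(contextual_inference_linear(c, W, 0.0), c)

    def test_zero_weights_identity(self):
        c = np.random.default_rng(3).random((2, 4, 4))
        out = contextual_inference_linear(c, np.zeros((2, 2, 3, 3)), 0.7)
        assert np.allclose(out, c, atol=1e-15)

    def test_single_entry_hand_formula(self):
        c = np.zeros((2, 5, 5))
        c[0, 2, 2] = 0.8
        c[1, 2, 3] = 0.5  # source one pixel right
        W = np.zeros((2, 2, 3, 3))
        W[0, 1, 1, 2] = 0.4  # target j=0 from k=1 at offset (0, +1)
        out = contextual_inference_linear(c, W, alpha=0.25)
        expect = c.copy()
        expect[0, 2, 2] = 0.8 * (1 + 0.25 * 0.4 * 0.5)
        assert np.allclose(out, expect, atol=1e-14)

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            contextual_inference_linear(np.zeros((1, 3, 3)),
                                        np.zeros((1, 1, 3, 3)), -0.1)

    def test_modulation_grows_with_alpha(self):
        rng = np.random.default_rng(4)
        c = rng.random((2, 6, 6))
        W = rng.uniform(0, 0.2, size=(2, 2, 3, 3))  # nonnegative surround
        dists = [np.linalg.norm(contextual_inference_linear(c, W, a) - c)
                 for a in (0.0, 0.1, 0.5, 1.0)]
        assert all(a <= b + 1e-12 for a, b in zip(dists, dists[1:]))

    def test_linear_matches_exact_to_second_order(self):
        """With several surround patches the product form and the linear
        form agree to O(alpha^2): halving alpha quarters the gap."""
        c = np.array([[[0.6, 0.9, 0.3]], [[0.4, 0.1, 0.7]]])
        base_W = np.zeros((2, 2, 1, 3))
        base_W[0, 0, 0, 0] = base_W[0, 0, 0, 2] = 0.3
        base_W[1, 1, 0, 0] = base_W[1, 1, 0, 2] = 0.2
        base_W[0, 1, 0, 0] = base_W[1, 0, 0, 2] = 0.1
        base_W[0, 1, 0, 2] = base_W[1, 0, 0, 0] = 0.1
        errs = []
        for alpha in (0.2, 0.1, 0.05):
            f_exact = contextual_inference_exact(c, alpha * base_W).values
            f_lin = contextual_inference_linear(c, base_W, alpha)
            f_lin = f_lin / f_lin.sum(axis=0)  # compare renormalized
            errs.append(np.abs(f_exact - f_lin).max())
        # second order: halving alpha should roughly quarter the gap
        assert errs[1] < 0.35 * errs[0]
        assert errs[2] < 0.35 * errs[1]


class TestSurroundStats:
    def test_zero_weights(self):
        c = [np.random.default_rng(5).random((2, 6, 6))]
        mean, sd = surround_effect_stats(c, np.zeros((2, 2, 3, 3)))
        assert mean == 0.0 and sd == 0.0

    def test_matches_naive_recomputation(self):
        rng = np.random.default_rng(6)
        maps = [rng.random((2, 5, 6)) for _ in range(2)]
        W = rng.standard_normal((2, 2, 3, 3))
        mean, sd = surround_effect_stats(maps, W)
        allS = np.concatenate([surround_term(m, W, method="direct").ravel()
                               for m in maps])
        assert mean == pytest.approx(allS.mean(), abs=1e-12)
        assert sd == pytest.approx(allS.std(), abs=1e-12)

    def test_fft_and_direct_agree(self):
        rng = np.random.default_rng(7)
        c = rng.random((4, 12, 11))
        W = rng.standard_normal((4, 4, 5, 5))
        a = surround_term(c, W, method="direct")
        b = surround_term(c, W, method="fft")
        assert np.allclose(a, b, atol=1e-12)


class TestContextConfig:
    def test_exact_requires_tiling(self):
        with pytest.raises(ValueError):
            ContextConfig(mode="exact", patch_scheme="dense")

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            ContextConfig(alpha=-1)
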