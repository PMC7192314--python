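import numpy as np
import pytest

import latnet.cnn_context as cc
from latnet.cnn_context import (
    ClassifierConfig, NoiseSpec, add_noise, build_variant, evaluate,
    learn_layer_lateral, normalize_activations, select_alpha,
    train_classifier,
)
from latnet.decomposition import split_components
from latnet.lateral import cooccurrence_weights
from latnet.synthetic import gen_toy_digits


@pytest.fixture(scope="module")
def digits():
    return gen_toy_digits(600, n_classes=4, seed=21)


@pytest.fixture(scope="module")
def tiny_cfg():
    return ClassifierConfig(conv_channels=(4, 8), fc_width=32, n_classes=4,
                            seeds=(0,), epochs=2, lr=0.05)


@pytest.fixture(scope="module")
def trained(tiny_cfg, digits):
    X, y = digits
    return train_classifier(tiny_cfg, X[:500], y[:500])[0]


class TestAddNoise:
    def test_awgn_level_zero_identity(self):
        x = np.random.default_rng(0).random((3, 8, 8))
        assert np.array_equal(add_noise(x, NoiseSpec("AWGN", 0.0, seed=1)), x)

    def test_awgn_clipped_to_unit_interval(self):
        x = np.random.default_rng(1).random((5, 10, 10))
        out = add_noise(x, NoiseSpec("AWGN", 0.5, seed=2))
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_spn_level_one_all_extreme(self):
        x = np.full((2, 6, 6), 0.5)
        out = add_noise(x, NoiseSpec("SPN", 1.0, seed=3))
        assert set(np.unique(out)) <= {0.0, 1.0}

    def test_spn_flips_exact_pixel_count(self):
        x = np.full((4, 28, 28), 0.5)  # every flip is visible
        out = add_noise(x, NoiseSpec("SPN", 0.3, seed=4))
        n_flip = int(round(0.3 * 784))
        for i in range(4):
            changed = np.flatnonzero(out[i].ravel() != 0.5)
            assert changed.size == n_flip
            assert set(np.unique(out[i].ravel()[changed])) <= {0.0, 1.0}

    def test_deterministic_per_seed(self):
        x = np.random.default_rng(5).random((2, 12, 12))
        spec = NoiseSpec("SPN", 0.2, seed=11)
        assert np.array_equal(add_noise(x, spec), add_noise(x, spec))

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            NoiseSpec("SPN", 1.5)


class TestTraining:
    def test_loss_decreases(self, trained):
        assert trained.losses[-1] < trained.losses[0]

    def test_same_seed_identical_weights(self, tiny_cfg, digits):
        X, y = digits
        a = train_classifier(tiny_cfg, X[:200], y[:200])[0]
        b = train_classifier(tiny_cfg, X[:200], y[:200])[0]
        for k in a.net.params:
            assert np.array_equal(a.net.params[k], b.net.params[k])

    def test_heldout_accuracy_on_toy_fixture(self):
        """2000 separable-by-construction glyphs train to > 90%."""
        X, y = gen_toy_digits(2000, n_classes=4, seed=31)
        cfg = ClassifierConfig(conv_channels=(4, 8), fc_width=32, n_classes=4,
                               seeds=(0,), epochs=3, lr=0.05)
        model = train_classifier(cfg, X[:1600], y[:1600])[0]
        acc = evaluate(model, build_variant("base"), X[1600:], y[1600:])
        assert acc > 90.0

    def test_empty_training_set_rejected(self, tiny_cfg):
        with pytest.raises(ValueError):
            train_classifier(tiny_cfg, np.empty((0, 28, 28)), np.empty(0))


class TestLayerLateral:
    def test_single_channel_reduces_to_autocorrelation_ratio(self, digits):
        X, y = digits
        cfg = ClassifierConfig(conv_channels=(1, 2), fc_width=16, n_classes=4,
                               seeds=(0,), epochs=1, lr=0.05)
        model = train_classifier(cfg, X[:100], y[:100])[0]
        lw = learn_layer_lateral(model, 1, X[:50], max_offset=2)
        assert lw.W.shape == (1, 1, 5, 5)
        # one channel: normalized activations are identically 1, whose
        # autocorrelation ratio - 1 vanishes everywhere
        assert np.allclose(lw.W, 0.0, atol=1e-12)

    def test_duplicated_channels_give_identical_weights(self, trained, digits):
        X, _ = digits
        net = trained.net
        saved = net.state_dict()
        try:
            net.params["W1"][1] = net.params["W1"][0]
            net.params["b1"][1] = net.params["b1"][0]
            lw = learn_layer_lateral(net, 1, X[:60], max_offset=2)
            assert np.allclose(lw.W[0, 0], lw.W[0, 1], atol=1e-10)
            assert np.allclose(lw.W[0, 0], lw.W[1, 1], atol=1e-10)
        finally:
            net.load_state_dict(saved)

    def test_agrees_with_cooccurrence_estimator(self, trained, digits):
        X, _ = digits
        lw = learn_layer_lateral(trained, 2, X[:40], max_offset=2)
        a1, a2 = trained.net.conv_activations(X[:40, None])
        maps = [normalize_activations(a) for a in a2]
        ref = cooccurrence_weights(maps, max_offset=2)
        assert np.allclose(lw.W, ref.W, atol=1e-12)

    def test_normalize_activations_probability_vectors(self):
        rng = np.random.default_rng(6)
        a = rng.standard_normal((3, 5, 4, 4))
        n = normalize_activations(a)
        assert np.allclose(n.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(n >= 0)


class TestVariants:
    def test_uniform_tensor_values(self):
        from latnet.cnn_context import _uniform_tensor
        W = _uniform_tensor((3, 3, 5, 5))
        n_t = 9 * 24
        assert W[0, 0, 0, 0] == pytest.approx(1.0 / n_t)
        assert W[0, 0, 2, 2] == 0.0

    def test_inhibition_only_assembly(self):
        rng = np.random.default_rng(7)
        shape = (3, 3, 3, 3)
        L = rng.standard_normal((3, 27))
        S = rng.standard_normal((3, 27)) * (rng.random((3, 27)) < 0.2)
        dec = split_components(L, S, 1.0, tensor_shape=shape)
        v_lr = build_variant("lowrank-inhibition-only", layer_decomps=(dec,),
                             alpha=0.1)
        v_s = build_variant("sparse-inhibition-only", layer_decomps=(dec,),
                            alpha=0.1)
        exc = dec.W_LR_pos + dec.W_S_pos
        assert np.allclose(v_lr.layer_weights[0],
                           (exc + dec.W_LR_neg).reshape(shape))
        assert np.allclose(v_s.layer_weights[0],
                           (exc + dec.W_S_neg).reshape(shape))

    def test_alpha_zero_reproduces_base_bit_exactly(self, trained, digits):
        X, y = digits
        x = X[:32, None]
        rng = np.random.default_rng(8)
        Wt = rng.standard_normal((4, 4, 5, 5))
        base_probs = trained.net.forward(x)
        var = cc.ContextVariant(name="full", layer_weights=(Wt, None), alpha=0.0)
        probs = trained.net.forward(x, modulators=cc._modulators(var))
        assert np.array_equal(base_probs, probs)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            cc.ContextVariant(name="nonsense")

    def test_missing_weights_rejected(self):
        with pytest.raises(ValueError):
            build_variant("full")


@pytest.fixture(scope="module")
def small_laterals(trained, digits):
    X, _ = digits
    return (learn_layer_lateral(trained, 1, X[:30], max_offset=1),
            learn_layer_lateral(trained, 2, X[:30], max_offset=1))


class TestSelectAlpha:
    def test_grid_of_zero_returns_zero(self, trained, small_laterals, digits,
                                       monkeypatch):
        X, y = digits
        monkeypatch.setattr(cc, "evaluate", lambda *a, **k: 50.0)
        alpha = select_alpha([trained], small_laterals, X[:10], y[:10],
                             grid=(0.0,))
        assert alpha == 0.0

    def test_flat_accuracy_ties_to_smallest(self, trained, small_laterals,
                                            digits, monkeypatch):
        X, y = digits
        monkeypatch.setattr(cc, "evaluate", lambda *a, **k: 75.0)
        alpha = select_alpha([trained], small_laterals, X[:10], y[:10],
                             grid=(0.3, 0.0, 1.0, 0.1))
        assert alpha == 0.0

    def test_planted_optimum_selected(self, trained, small_laterals, digits,
                                      monkeypatch):
        X, y = digits

        def fake_eval(models, variant, *a, **k):
            return 100.0 - abs(variant.alpha - 0.2) * 10

        monkeypatch.setattr(cc, "evaluate", fake_eval)
        alpha = select_alpha([trained], small_laterals, X[:10], y[:10],
                             grid=(0.0, 0.1, 0.2, 0.3, 1.0))
        assert alpha == 0.2

    def test_empty_validation_rejected(self, trained):
        with pytest.raises(ValueError):
            select_alpha([trained], (), np.empty((0, 28, 28)), np.empty(0))
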