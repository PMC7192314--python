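"""Lateral connections inside a small convolutional classifier.

Workflow: train a 2-conv / 2-FC softmax classifier on clean images; with
its filters frozen, learn lateral weights between channels of each conv
layer from the co-occurrence statistics of their (divisively normalized)
activations over the training set; decompose each layer's tensor into
signed low-rank / sparse components; and at test time modulate the
post-ReLU conv activations with the linearized surround term
``a * (1 + alpha * S)`` before pooling.  The surround strength ``alpha``
is chosen on held-out validation data.  Noise robustness is probed with
additive white Gaussian noise and salt-and-pepper noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decomposition import RPCAConfig, WeightDecomposition, decompose_weights
from .lateral import LateralWeights, cooccurrence_weights
from .nn import SmallCNN

__all__ = [
    "ClassifierConfig",
    "NoiseSpec",
    "ContextVariant",
    "add_noise",
    "train_classifier",
    "learn_layer_lateral",
    "normalize_activations",
    "build_variant",
    "evaluate",
    "select_alpha",
]

VARIANT_NAMES = ("base", "full", "uniform-avg",
                 "lowrank-inhibition-only", "sparse-inhibition-only")

#: RPCA trade-off used when decomposing the two conv layers' tensors
LAYER_BETAS = (0.1, 0.25)


@dataclass(frozen=True)
class ClassifierConfig:
    """Architecture and training settings for the small classifier."""

    conv_channels: tuple[int, int] = (32, 64)
    kernel_sizes: tuple[int, int] = (5, 5)
    pool_sizes: tuple[int, int] = (2, 2)
    fc_width: int = 128
    n_classes: int = 10
    seeds: tuple[int, ...] = tuple(range(10))
    lr: float = 0.1
    momentum: float = 0.9
    batch_size: int = 64
    epochs: int = 5
    val_fraction: float = 0.1

    def __post_init__(self) -> None:
        if len(self.conv_channels) != 2 or len(self.kernel_sizes) != 2:
            raise ValueError("exactly two conv layers are supported")
        if self.pool_sizes != (2, 2):
            raise ValueError("only 2x2 max pooling is supported")
        if not 0 <= self.val_fraction < 1:
            raise ValueError("val_fraction must be in [0, 1)")


@dataclass(frozen=True)
class NoiseSpec:
    """Test-time image corruption.

    kind : "AWGN" (additive white Gaussian noise with standard deviation
        ``level``, clipped back to [0, 1]) or "SPN" (salt-and-pepper: a
        fraction ``level`` of pixels forced to 0 or 1, half/half in
        expectation).
    """

    kind: str
    level: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("AWGN", "SPN"):
            raise ValueError("kind must be 'AWGN' or 'SPN'")
        if not 0.0 <= self.level <= 1.0:
            raise ValueError("level must be in [0, 1]")


def add_noise(images: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Apply the specified corruption; deterministic per seed."""
    x = np.asarray(images, float)
    if x.min() < 0 or x.max() > 1:
        raise ValueError("images must lie in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "AWGN":
        return np.clip(x + rng.normal(0.0, spec.level, size=x.shape), 0.0, 1.0)
    flat = x.reshape(len(x), -1).copy()
    n_px = flat.shape[1]
    n_flip = int(round(spec.level * n_px))
    for i in range(len(flat)):
        pos = rng.choice(n_px, size=n_flip, replace=False)
        flat[i, pos] = (rng.random(n_flip) < 0.5).astype(float)
    return flat.reshape(x.shape)


@dataclass
class TrainedModel:
    """A trained classifier plus its training trace."""

    net: SmallCNN
    seed: int
    losses: list = field(default_factory=list)
    config: ClassifierConfig | None = None


def train_classifier(
    cfg: ClassifierConfig,
    images: np.ndarray,
    labels: np.ndarray,
    verbose: bool = False,
) -> list[TrainedModel]:
    """Train one model per seed with minibatch SGD; deterministic per seed."""
    x = _as_nchw(images)
    y = np.asarray(labels)
    if len(x) == 0:
        raise ValueError("empty training set")
    models = []
    for seed in cfg.seeds:
        net = SmallCNN(
            in_shape=x.shape[1:],
            conv_channels=cfg.conv_channels,
            kernel_sizes=cfg.kernel_sizes,
            fc_width=cfg.fc_width,
            n_classes=cfg.n_classes,
            seed=seed,
        )
        rng = np.random.default_rng(seed + 1_000_003)
        losses = []
        for ep in range(cfg.epochs):
            loss = net.train_epoch(x, y, rng, batch_size=cfg.batch_size,
                                   lr=cfg.lr, momentum=cfg.momentum)
            losses.append(loss)
            if verbose:
                print(f"seed {seed} epoch {ep}: loss {loss:.4f}")
        models.append(TrainedModel(net=net, seed=seed, losses=losses, config=cfg))
    return models


def _as_nchw(images: np.ndarray) -> np.ndarray:
    x = np.asarray(images, float)
    if x.ndim == 3:
        x = x[:, None]
    if x.ndim != 4:
        raise ValueError("images must be (N, H, W) or (N, C, H, W)")
    return x


def normalize_activations(acts: np.ndarray) -> np.ndarray:
    """Divisive normalization across channels at each location.

    Rectified activations are divided by their channel sum per location so
    they form probability vectors; all-zero locations get the uniform
    vector (no evidence).  Used only when *learning* lateral weights —
    inference modulates the raw activations.
    """
    a = np.maximum(np.asarray(acts, float), 0.0)
    tot = a.sum(axis=-3, keepdims=True)
    K = a.shape[-3]
    out = np.where(tot > 0, a / np.where(tot > 0, tot, 1.0), 1.0 / K)
    return out


def learn_layer_lateral(
    model: TrainedModel | SmallCNN,
    layer: int,
    images: np.ndarray,
    max_offset: int | None = None,
    offset_fraction: float = 0.25,
    batch_size: int = 256,
) -> LateralWeights:
    """Learn lateral weights between one conv layer's channels.

    The layer's post-ReLU, pre-pool activations over the images are
    divisively normalized across channels per location, then pooled into
    the co-occurrence weight estimate exactly as for image responses.
    ``max_offset`` defaults to ``offset_fraction`` of the feature-map
    side.  Dead channels (zero mean activation) are zeroed with a warning
    by the estimator.
    """
    net = model.net if isinstance(model, TrainedModel) else model
    if layer not in (1, 2):
        raise ValueError("layer must be 1 or 2")
    x = _as_nchw(images)
    norm_maps = []
    for start in range(0, len(x), batch_size):
        a1, a2 = net.conv_activations(x[start:start + batch_size])
        acts = a1 if layer == 1 else a2
        norm_maps.extend(normalize_activations(acts))
    side = norm_maps[0].shape[-1]
    if max_offset is None:
        max_offset = max(1, int(round(offset_fraction * side)))
    return cooccurrence_weights(norm_maps, max_offset=max_offset,
                                bank_ref=f"conv{layer}")


@dataclass
class ContextVariant:
    """A lateral-connection configuration to evaluate.

    name : one of base / full / uniform-avg / lowrank-inhibition-only /
        sparse-inhibition-only.
    layer_weights : per conv layer, the 4-D weight tensor to use (None
        for the base model).
    alpha : surround strength, shared across layers.
    """

    name: str
    layer_weights: tuple[np.ndarray | None, ...] = (None, None)
    alpha: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in VARIANT_NAMES:
            raise ValueError(f"unknown variant {self.name!r}")


def _uniform_tensor(shape: tuple) -> np.ndarray:
    """Uniform control: every lateral connection carries 1/N_T.

    ``N_T`` is the total number of lateral connections in the layer's
    weight tensor (all channel pairs and nonzero offsets).
    """
    K, _, n, _ = shape
    n_t = K * K * (n * n - 1)
    W = np.full(shape, 1.0 / n_t)
    W[:, :, n // 2, n // 2] = 0.0
    return W


def build_variant(
    name: str,
    layer_laterals: tuple[LateralWeights, ...] = (),
    layer_decomps: tuple[WeightDecomposition, ...] = (),
    alpha: float = 0.0,
) -> ContextVariant:
    """Assemble the weight tensors for a named variant.

    full uses the learned tensors as-is; uniform-avg replaces them with
    the 1/N_T control; the *-inhibition-only variants keep both excitatory
    components but only one of the two inhibitory ones.
    """
    if name == "base":
        return ContextVariant(name=name, layer_weights=(None, None), alpha=0.0)
    if name == "full":
        if not layer_laterals:
            raise ValueError("full variant requires learned lateral weights")
        return ContextVariant(
            name=name,
            layer_weights=tuple(lw.W for lw in layer_laterals),
            alpha=alpha,
        )
    if name == "uniform-avg":
        if not layer_laterals:
            raise ValueError("uniform-avg requires tensors to size the control")
        return ContextVariant(
            name=name,
            layer_weights=tuple(_uniform_tensor(lw.W.shape) for lw in layer_laterals),
            alpha=alpha,
        )
    if name in ("lowrank-inhibition-only", "sparse-inhibition-only"):
        if not layer_decomps:
            raise ValueError(f"{name} requires per-layer decompositions")
        tensors = []
        for dec in layer_decomps:
            shape = dec.tensor_shape
            if shape is None:
                raise ValueError("decomposition lacks tensor_shape")
            exc = dec.W_LR_pos + dec.W_S_pos
            inh = dec.W_LR_neg if name.startswith("lowrank") else dec.W_S_neg
            tensors.append((exc + inh).reshape(shape))
        return ContextVariant(name=name, layer_weights=tuple(tensors), alpha=alpha)
    raise ValueError(f"unknown variant {name!r}")


def _modulators(variant: ContextVariant):
    """Per-layer callables applying f = a * (1 + alpha * S) batchwise."""
    if variant.alpha == 0.0:
        return (None, None)

    def make(Wt):
        if Wt is None:
            return None
        Wd = np.asarray(Wt, float).copy()
        ry, rx = Wd.shape[2] // 2, Wd.shape[3] // 2
        Wd[:, :, ry, rx] = 0.0
        kern_flip = Wd[:, :, ::-1, ::-1]
        alpha = variant.alpha

        def mod(acts: np.ndarray) -> np.ndarray:
            N, K, H, Wi = acts.shape
            PH, PW = H + 2 * ry, Wi + 2 * rx
            Fc = np.fft.rfft2(acts, s=(PH, PW))
            Fw = np.fft.rfft2(kern_flip, s=(PH, PW))
            FS = np.einsum("nkhw,jkhw->njhw", Fc, Fw)
            S = np.fft.irfft2(FS, s=(PH, PW))[:, :, ry:ry + H, rx:rx + Wi]
            return np.maximum(acts * (1.0 + alpha * S), 0.0)

        return mod

    return tuple(make(Wt) for Wt in variant.layer_weights)


def evaluate(
    models,
    variant: ContextVariant,
    images: np.ndarray,
    labels: np.ndarray,
    noise: NoiseSpec | None = None,
    batch_size: int = 256,
) -> float:
    """Mean accuracy (%) of a variant over the trained models."""
    if isinstance(models, TrainedModel):
        models = [models]
    x = _as_nchw(images if noise is None else add_noise(images, noise))
    y = np.asarray(labels)
    mods = _modulators(variant)
    accs = []
    for m in models:
        net = m.net if isinstance(m, TrainedModel) else m
        pred = net.predict(x, modulators=mods, batch_size=batch_size)
        accs.append(100.0 * float(np.mean(pred == y)))
    return float(np.mean(accs))


def select_alpha(
    models,
    layer_laterals,
    val_images: np.ndarray,
    val_labels: np.ndarray,
    grid=(0.0, 0.01, 0.03, 0.1, 0.3, 1.0),
    noise_specs: tuple[NoiseSpec, ...] = (),
    variant_name: str = "full",
    layer_decomps=(),
) -> float:
    """Grid-search the surround strength on held-out validation data.

    Validation accuracy is averaged over the given noise specs (plus the
    clean images if none are given); ties break toward the smaller alpha.
    """
    if len(val_images) == 0 or len(tuple(grid)) == 0:
        raise ValueError("need a nonempty validation set and grid")
    specs: tuple = noise_specs if noise_specs else (None,)
    best_alpha, best_acc = None, -np.inf
    for alpha in sorted(grid):
        variant = build_variant(variant_name, layer_laterals=layer_laterals,
                                layer_decomps=layer_decomps, alpha=alpha)
        acc = float(np.mean([
            evaluate(models, variant, val_images, val_labels, noise=spec)
            for spec in specs
        ]))
        if acc > best_acc + 1e-12:  # strict improvement; ties keep smaller alpha
            best_alpha, best_acc = alpha, acc
    return float(best_alpha)


def run_context_experiment(
    cfg: ClassifierConfig,
    images: np.ndarray,
    labels: np.ndarray,
    eval_noise: tuple[NoiseSpec, ...],
    selection_noise: tuple[NoiseSpec, ...] = (),
    variants: tuple[str, ...] = VARIANT_NAMES,
    alpha_grid=(0.0, 0.01, 0.03, 0.1, 0.3, 1.0),
    max_offsets: tuple[int, int] = (5, 2),
    n_test: int = 500,
    n_lateral_images: int = 800,
    layer_betas: tuple[float, float] = LAYER_BETAS,
    seed: int = 0,
    verbose: bool = False,
) -> dict:
    """Full noise-robustness protocol, averaged over model seeds.

    The data are split (shuffled by ``seed``) into train / validation /
    test; one classifier is trained per config seed; each model's lateral
    tensors are learned from its own conv activations on (a subsample of)
    the training images and decomposed with the per-layer RPCA trade-offs;
    a single surround strength is selected per model on the validation
    set with the ``full`` variant under ``selection_noise`` and reused for
    every lateral variant.  Returns per-variant mean accuracies (%) for
    the clean test set and for each evaluation noise spec, plus the
    selected alphas.
    """
    rng = np.random.default_rng(seed)
    x = _as_nchw(images)
    y = np.asarray(labels)
    order = rng.permutation(len(x))
    x, y = x[order], y[order]
    n_val = max(1, int(round(cfg.val_fraction * (len(x) - n_test))))
    x_test, y_test = x[:n_test], y[:n_test]
    x_val, y_val = x[n_test:n_test + n_val], y[n_test:n_test + n_val]
    x_tr, y_tr = x[n_test + n_val:], y[n_test + n_val:]

    models = train_classifier(cfg, x_tr, y_tr, verbose=verbose)
    x_lat = x_tr[:n_lateral_images]

    results: dict = {
        "alphas": [],
        "accuracy": {v: {"clean": []} for v in variants},
        "n_train": len(x_tr), "n_val": len(x_val), "n_test": len(x_test),
    }
    for spec in eval_noise:
        for v in variants:
            results["accuracy"][v][_noise_key(spec)] = []

    for m in models:
        laterals = tuple(
            learn_layer_lateral(m, layer, x_lat, max_offset=off)
            for layer, off in zip((1, 2), max_offsets)
        )
        need_decomp = any(v.endswith("-only") for v in variants)
        decomps = tuple(
            decompose_layer(lw, beta=beta)
            for lw, beta in zip(laterals, layer_betas)
        ) if need_decomp else ()

        alpha = select_alpha(
            [m], laterals, x_val, y_val, grid=alpha_grid,
            noise_specs=selection_noise,
        )
        results["alphas"].append(alpha)
        if verbose:
            print(f"seed {m.seed}: alpha={alpha}")

        for name in variants:
            var = build_variant(name, layer_laterals=laterals,
                                layer_decomps=decomps,
                                alpha=0.0 if name == "base" else alpha)
            results["accuracy"][name]["clean"].append(
                evaluate([m], var, x_test, y_test))
            for spec in eval_noise:
                results["accuracy"][name][_noise_key(spec)].append(
                    evaluate([m], var, x_test, y_test, noise=spec))

    results["mean_accuracy"] = {
        v: {k: float(np.mean(a)) for k, a in d.items()}
        for v, d in results["accuracy"].items()
    }
    return results


def _noise_key(spec: NoiseSpec) -> str:
    return f"{spec.kind}_{spec.level:g}"


def decompose_layer(
    lw: LateralWeights,
    beta: float,
    gamma: float = 1.0,
    **kwargs,
) -> WeightDecomposition:
    """RPCA decomposition of a layer's lateral tensor at the given beta."""
    cfg = RPCAConfig(beta=beta, gamma=gamma, **kwargs)
    return decompose_weights(lw, cfg)
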