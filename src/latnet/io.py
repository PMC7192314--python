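"""Readers and writers: images, MNIST-format IDX files, HDF5 artifacts.

All weight artifacts (filter banks, lateral weight tensors,
decompositions, model checkpoints) round-trip bit-exactly through HDF5
groups with a schema version attribute.
"""

from __future__ import annotations

import struct
from pathlib import Path

import h5py
import numpy as np
from PIL import Image

from .decomposition import WeightDecomposition
from .filterbank import FilterBank
from .lateral import LateralWeights

__all__ = [
    "load_images",
    "read_mnist_idx",
    "save_filterbank", "load_filterbank",
    "save_lateral_weights", "load_lateral_weights",
    "save_decomposition", "load_decomposition",
    "save_model", "load_model",
]

SCHEMA_VERSION = 1
_IMG_EXTS = {".png", ".jpg", ".jpeg"}


def load_images(source) -> list[np.ndarray]:
    """Load PNG/JPEG images as float arrays in [0, 1], sorted by path.

    ``source`` is a directory or an iterable of file paths.  8- and 16-bit
    integer images are scaled by their type maximum; an unreadable file
    raises an error naming it.
    """
    src = Path(source) if isinstance(source, (str, Path)) else None
    if src is not None:
        if not src.is_dir():
            paths = [src]
        else:
            paths = sorted(p for p in src.iterdir() if p.suffix.lower() in _IMG_EXTS)
            if not paths:
                import warnings
                warnings.warn(f"no images found in {src}", RuntimeWarning)
    else:
        paths = [Path(p) for p in sorted(map(str, source))]

    out = []
    for p in paths:
        try:
            with Image.open(p) as im:
                arr = np.asarray(im)
        except Exception as err:
            raise IOError(f"cannot read image {p}: {err}") from err
        if np.issubdtype(arr.dtype, np.integer):
            arr = arr.astype(float) / np.iinfo(arr.dtype).max
        else:
            arr = arr.astype(float)
        out.append(arr)
    return out


_IDX_IMAGES_MAGIC = 2051
_IDX_LABELS_MAGIC = 2049


def read_mnist_idx(images_path, labels_path) -> tuple[np.ndarray, np.ndarray]:
    """Read an IDX image/label file pair (the MNIST byte layout).

    Big-endian headers; pixel bytes are scaled to [0, 1].  Magic-number,
    byte-count, label-range and image/label count mismatches are rejected
    with both values reported.
    """
    img_bytes = Path(images_path).read_bytes()
    lab_bytes = Path(labels_path).read_bytes()

    if len(img_bytes) < 16:
        raise ValueError(f"image file truncated: {len(img_bytes)} < 16 header bytes")
    magic, n, rows, cols = struct.unpack(">iiii", img_bytes[:16])
    if magic != _IDX_IMAGES_MAGIC:
        raise ValueError(f"bad image magic: expected {_IDX_IMAGES_MAGIC}, got {magic}")
    expected = 16 + n * rows * cols
    if len(img_bytes) != expected:
        raise ValueError(
            f"image file length mismatch: expected {expected} bytes, got {len(img_bytes)}"
        )
    images = np.frombuffer(img_bytes, dtype=np.uint8, offset=16)
    images = images.reshape(n, rows, cols).astype(float) / 255.0

    if len(lab_bytes) < 8:
        raise ValueError(f"label file truncated: {len(lab_bytes)} < 8 header bytes")
    lmagic, ln = struct.unpack(">ii", lab_bytes[:8])
    if lmagic != _IDX_LABELS_MAGIC:
        raise ValueError(f"bad label magic: expected {_IDX_LABELS_MAGIC}, got {lmagic}")
    if len(lab_bytes) != 8 + ln:
        raise ValueError(
            f"label file length mismatch: expected {8 + ln} bytes, got {len(lab_bytes)}"
        )
    labels = np.frombuffer(lab_bytes, dtype=np.uint8, offset=8).astype(np.int64)
    if n != ln:
        raise ValueError(f"image count {n} != label count {ln}")
    if labels.size and (labels.min() < 0 or labels.max() > 9):
        raise ValueError(f"labels outside 0-9: range {labels.min()}-{labels.max()}")
    return images, labels


# ------------------------------------------------------------------- HDF5

def _check_schema(grp: h5py.Group, kind: str) -> None:
    ver = grp.attrs.get("schema_version")
    if ver is None:
        raise ValueError(f"{kind}: missing schema_version attribute")
    if int(ver) != SCHEMA_VERSION:
        raise ValueError(
            f"{kind}: schema version {ver} != supported {SCHEMA_VERSION}"
        )


def _open(path_or_group, mode):
    if isinstance(path_or_group, h5py.Group):
        return path_or_group, False
    return h5py.File(path_or_group, mode), True


def save_filterbank(bank: FilterBank, target) -> None:
    grp, close = _open(target, "w")
    try:
        grp.attrs["schema_version"] = SCHEMA_VERSION
        grp.attrs["kind"] = "filterbank"
        grp.attrs["name"] = bank.name
        grp.attrs["deg_per_px"] = bank.deg_per_px
        grp.create_dataset("filters", data=bank.filters)
        grp.create_dataset("classes", data=np.array(bank.classes, dtype="S"))
        grp.create_dataset("relative_orientation", data=bank.relative_orientation)
        grp.create_dataset("preferred_orientation", data=bank.preferred_orientation)
    finally:
        if close:
            grp.close()


def load_filterbank(source) -> FilterBank:
    grp, close = _open(source, "r")
    try:
        _check_schema(grp, "filterbank")
        return FilterBank(
            filters=grp["filters"][()],
            classes=[c.decode() for c in grp["classes"][()]],
            relative_orientation=grp["relative_orientation"][()],
            preferred_orientation=grp["preferred_orientation"][()],
            deg_per_px=float(grp.attrs["deg_per_px"]),
            name=str(grp.attrs["name"]),
        )
    finally:
        if close:
            grp.close()


def save_lateral_weights(lw: LateralWeights, target) -> None:
    grp, close = _open(target, "w")
    try:
        grp.attrs["schema_version"] = SCHEMA_VERSION
        grp.attrs["kind"] = "lateral_weights"
        grp.attrs["n_images"] = lw.n_images
        grp.attrs["bank_ref"] = lw.bank_ref
        grp.attrs["masked"] = lw.masked
        grp.create_dataset("W", data=lw.W)
        grp.create_dataset("n_samples", data=lw.n_samples)
        grp.create_dataset("feature_means", data=lw.feature_means)
    finally:
        if close:
            grp.close()


def load_lateral_weights(source) -> LateralWeights:
    grp, close = _open(source, "r")
    try:
        _check_schema(grp, "lateral_weights")
        return LateralWeights(
            W=grp["W"][()],
            n_images=int(grp.attrs["n_images"]),
            n_samples=grp["n_samples"][()],
            feature_means=grp["feature_means"][()],
            bank_ref=str(grp.attrs["bank_ref"]),
            masked=bool(grp.attrs["masked"]),
        )
    finally:
        if close:
            grp.close()


_DECOMP_ARRAYS = ("L", "S", "W_LR_pos", "W_LR_neg", "W_S_pos", "W_S_neg",
                  "singular_values")


def save_decomposition(dec: WeightDecomposition, target) -> None:
    grp, close = _open(target, "w")
    try:
        grp.attrs["schema_version"] = SCHEMA_VERSION
        grp.attrs["kind"] = "decomposition"
        for name in _DECOMP_ARRAYS:
            grp.create_dataset(name, data=getattr(dec, name))
        grp.attrs["retained_rank"] = dec.retained_rank
        grp.attrs["sparsity_entries"] = dec.sparsity_entries
        grp.attrs["sparsity_columns"] = dec.sparsity_columns
        grp.attrs["converged"] = dec.converged
        grp.attrs["n_iter"] = dec.n_iter
        grp.attrs["residual"] = dec.residual
        if dec.tensor_shape is not None:
            grp.attrs["tensor_shape"] = np.array(dec.tensor_shape)
    finally:
        if close:
            grp.close()


def save_model(net, target) -> None:
    """Checkpoint a classifier's parameters and architecture metadata."""
    grp, close = _open(target, "w")
    try:
        grp.attrs["schema_version"] = SCHEMA_VERSION
        grp.attrs["kind"] = "model"
        grp.attrs["seed"] = net.seed
        grp.attrs["in_shape"] = np.array(net.in_shape)
        grp.attrs["n_classes"] = net.n_classes
        for k, v in net.params.items():
            grp.create_dataset(k, data=v)
    finally:
        if close:
            grp.close()


def load_model(source):
    from .nn import SmallCNN

    grp, close = _open(source, "r")
    try:
        _check_schema(grp, "model")
        state = {k: grp[k][()] for k in grp.keys()}
        net = SmallCNN(
            in_shape=tuple(int(s) for s in grp.attrs["in_shape"]),
            conv_channels=(state["W1"].shape[0], state["W2"].shape[0]),
            kernel_sizes=(state["W1"].shape[2], state["W2"].shape[2]),
            fc_width=state["W3"].shape[1],
            n_classes=int(grp.attrs["n_classes"]),
            seed=int(grp.attrs["seed"]),
        )
        net.load_state_dict(state)
        return net
    finally:
        if close:
            grp.close()


def load_decomposition(source) -> WeightDecomposition:
    grp, close = _open(source, "r")
    try:
        _check_schema(grp, "decomposition")
        shape = grp.attrs.get("tensor_shape")
        return WeightDecomposition(
            **{name: grp[name][()] for name in _DECOMP_ARRAYS},
            retained_rank=int(grp.attrs["retained_rank"]),
            sparsity_entries=float(grp.attrs["sparsity_entries"]),
            sparsity_columns=float(grp.attrs["sparsity_columns"]),
            converged=bool(grp.attrs["converged"]),
            n_iter=int(grp.attrs["n_iter"]),
            residual=float(grp.attrs["residual"]),
            tensor_shape=tuple(int(s) for s in shape) if shape is not None else None,
        )
    finally:
        if close:
            grp.close()
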