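"""Lateral connection weights from feature co-occurrence statistics.

The weight from a source unit coding feature ``k`` at spatial offset
``(dy, dx)`` onto a target unit coding feature ``j`` is the relative
probability of co-occurrence above chance,

    W[j, k, dy, dx] = <c_j(m) c_k(m + d)> / (<c_j> <c_k>) - 1,

with expectations pooled over all images and all valid positions ``m``
(translation invariance).  W is 0 for independent features and -1 for
mutually exclusive ones, and is symmetric under exchanging source and
target together with inverting the offset.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .responses import ResponseMap

__all__ = ["LateralWeights", "cooccurrence_weights", "mask_overlap"]

logger = logging.getLogger(__name__)


@dataclass
class LateralWeights:
    """4-D lateral weight tensor over feature pairs and spatial offsets.

    Attributes
    ----------
    W : (J, K, n_off, n_off) ndarray
        Weight from source feature ``k`` at offset ``(dy, dx)`` to target
        feature ``j``; the offset grid has odd side ``2*max_offset + 1``
        with index ``max_offset`` at offset zero.  Offsets follow image
        convention: dy downward, dx rightward, source = target + (dy, dx).
    n_images : int
        Number of images pooled.
    n_samples : (n_off, n_off) ndarray
        Number of valid position pairs that contributed per offset.
    feature_means : (J,) ndarray
        Pooled mean response per feature (the normalization denominator).
    masked : bool
        Whether overlapping-RF offsets have been zeroed.
    """

    W: np.ndarray
    n_images: int
    n_samples: np.ndarray
    feature_means: np.ndarray
    bank_ref: str = ""
    masked: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def max_offset(self) -> int:
        return self.W.shape[2] // 2

    @property
    def offsets(self) -> np.ndarray:
        """Integer offsets along one axis, ``[-max_offset, ..., max_offset]``."""
        r = self.max_offset
        return np.arange(-r, r + 1)

    def validate(self) -> None:
        J, K, A, B = self.W.shape
        if J != K or A != B or A % 2 == 0:
            raise ValueError(f"bad weight tensor shape {self.W.shape}")
        if np.nanmin(self.W) < -1.0 - 1e-9:
            raise ValueError("weight below the -1 bound")
        # exchange symmetry: W[j,k,d] == W[k,j,-d]
        flipped = self.W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        if not np.array_equal(np.nan_to_num(self.W), np.nan_to_num(flipped)):
            raise ValueError("exchange symmetry violated")


def _as_value_arrays(responses: Iterable) -> list[np.ndarray]:
    out = []
    for r in responses:
        out.append(r.values if isinstance(r, ResponseMap) else np.asarray(r, float))
    if not out:
        raise ValueError("need at least one response map")
    K = out[0].shape[0]
    for v in out:
        if v.ndim != 3 or v.shape[0] != K:
            raise ValueError("response maps must share the feature dimension")
    return out


def _pair_sums_direct(v: np.ndarray, max_offset: int) -> np.ndarray:
    """Sum over positions (and any batch axis) of c_j(m) c_k(m+d)."""
    if v.ndim == 3:
        v = v[None]
    B, K, H, W = v.shape
    n = 2 * max_offset + 1
    out = np.zeros((K, K, n, n))
    for iy, dy in enumerate(range(-max_offset, max_offset + 1)):
        y0, y1 = max(0, -dy), min(H, H - dy)
        if y1 <= y0:
            continue
        for ix, dx in enumerate(range(-max_offset, max_offset + 1)):
            x0, x1 = max(0, -dx), min(W, W - dx)
            if x1 <= x0:
                continue
            a = v[:, :, y0:y1, x0:x1].reshape(B, K, -1)
            b = v[:, :, y0 + dy:y1 + dy, x0 + dx:x1 + dx].reshape(B, K, -1)
            out[:, :, iy, ix] = np.einsum("bjl,bkl->jk", a, b)
    return out


def _pair_sums_fft(v: np.ndarray, max_offset: int) -> np.ndarray:
    """Same pair sums via zero-padded FFT cross-correlation."""
    K, H, W = v.shape
    r = max_offset
    PH, PW = H + 2 * r, W + 2 * r
    F = np.fft.rfft2(v, s=(PH, PW))
    prod = np.conj(F)[:, None] * F[None, :]
    corr = np.fft.irfft2(prod, s=(PH, PW))
    # linear correlation value at offset d sits at index d mod padded size
    idx_y = np.arange(-r, r + 1) % PH
    idx_x = np.arange(-r, r + 1) % PW
    return corr[:, :, idx_y[:, None], idx_x[None, :]]


def _offset_counts(H: int, W: int, max_offset: int) -> np.ndarray:
    r = max_offset
    dy = np.arange(-r, r + 1)
    dx = np.arange(-r, r + 1)
    cy = np.clip(H - np.abs(dy), 0, None)
    cx = np.clip(W - np.abs(dx), 0, None)
    return cy[:, None] * cx[None, :]


def cooccurrence_weights(
    responses: Sequence[ResponseMap] | Sequence[np.ndarray],
    max_offset: int = 21,
    method: str = "auto",
    bank_ref: str | None = None,
) -> LateralWeights:
    """Estimate the lateral weight tensor from response maps.

    Expectations pool over every image and every position pair where both
    the target location ``m`` and the source location ``m + d`` are inside
    the map; per-offset sample counts are recorded.  Features whose pooled
    mean response is zero have an undefined ratio: their rows and columns
    are set to 0 with a warning.

    ``method`` selects the pair-sum path: ``"direct"`` (exact summation),
    ``"fft"`` (zero-padded cross-correlation), or ``"auto"``.
    """
    if max_offset < 1:
        raise ValueError("max_offset must be >= 1")
    values = _as_value_arrays(responses)
    K = values[0].shape[0]
    n = 2 * max_offset + 1

    if method == "auto":
        work = sum(v.shape[1] * v.shape[2] for v in values) * n * n * K
        method = "fft" if work > 5e7 else "direct"
    if method not in ("direct", "fft"):
        raise ValueError("method must be 'auto', 'direct' or 'fft'")
    pair_fn = _pair_sums_fft if method == "fft" else _pair_sums_direct

    pair_sums = np.zeros((K, K, n, n))
    counts = np.zeros((n, n), dtype=np.int64)
    feat_sum = np.zeros(K)
    n_pos = 0

    # group equal-shaped maps so the direct path can batch them
    by_shape: dict[tuple, list[np.ndarray]] = {}
    for v in values:
        by_shape.setdefault(v.shape, []).append(v)
    for shape, group in by_shape.items():
        H, W = shape[1], shape[2]
        if H <= max_offset or W <= max_offset:
            logger.warning(
                "map %s has fewer pixels than max_offset=%d along an axis",
                shape, max_offset,
            )
        if method == "direct":
            batch = np.stack(group)
            pair_sums += _pair_sums_direct(batch, max_offset)
            feat_sum += batch.sum(axis=(0, 2, 3))
        else:
            for v in group:
                pair_sums += pair_fn(v, max_offset)
                feat_sum += v.sum(axis=(1, 2))
        counts += len(group) * _offset_counts(H, W, max_offset)
        n_pos += len(group) * H * W

    means = feat_sum / n_pos
    zero = means == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} feature(s) with zero mean response; "
            "their weights are set to 0",
            RuntimeWarning,
        )
    safe_means = np.where(zero, 1.0, means)

    with np.errstate(invalid="ignore", divide="ignore"):
        cross = np.where(counts > 0, pair_sums / counts, 0.0)
    W4 = cross / (safe_means[:, None, None, None] * safe_means[None, :, None, None]) - 1.0
    W4[:, :, counts == 0] = 0.0
    W4[zero, :, :, :] = 0.0
    W4[:, zero, :, :] = 0.0

    # enforce exact exchange symmetry W[j,k,d] = W[k,j,-d] (holds up to
    # floating-point summation order; symmetrize to make it bit-exact)
    W4 = 0.5 * (W4 + W4[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))

    lw = LateralWeights(
        W=W4,
        n_images=len(values),
        n_samples=counts,
        feature_means=means,
        bank_ref=bank_ref or getattr(responses[0], "bank_ref", ""),
        meta={"method": method},
    )
    lw.validate()
    return lw


def mask_overlap(lw: LateralWeights, rf_size: int) -> LateralWeights:
    """Zero out offsets where source and target receptive fields overlap.

    Entries with Chebyshev distance ``max(|dy|, |dx|) < rf_size`` are set
    to 0; the returned tensor is flagged ``masked``.  ``rf_size = 0`` is
    the identity.
    """
    r = lw.max_offset
    if rf_size > 2 * r + 1:
        raise ValueError("rf_size exceeds the offset extent")
    d = np.arange(-r, r + 1)
    cheb = np.maximum(np.abs(d)[:, None], np.abs(d)[None, :])
    W = lw.W.copy()
    W[:, :, cheb < rf_size] = 0.0
    out = replace(lw, W=W, masked=True)
    out.validate()
    return out
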