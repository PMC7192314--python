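"""Contextual inference: combining feedforward evidence with the surround.

Two forms are provided.  The *exact* product form applies to disjoint,
non-overlapping patches (the independence regime of its derivation): the
feedforward probability of each feature is multiplied by one bracket
``1 + sum_k W[j,k,d] c_k(n)`` per surround patch, then renormalized so the
features at each patch again form a probability vector.  The *linear* form
keeps only the first-order surround contribution,

    f = c * (1 + alpha * S),    S[j, m] = sum_k sum_{d != 0} W[j,k,d] c[k, m+d],

with a tunable surround strength ``alpha``; it applies to dense feature
maps (including CNN activations) and does not renormalize.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .lateral import LateralWeights
from .responses import ResponseMap

__all__ = [
    "ContextConfig",
    "contextual_inference_exact",
    "contextual_inference_linear",
    "surround_term",
    "surround_effect_stats",
]


@dataclass(frozen=True)
class ContextConfig:
    """Surround-integration settings.

    alpha : surround strength (>= 0) for the linear form.
    mode : "exact" (product form on tiled patches) or "linear".
    patch_scheme : "tiling" (disjoint patches; required by exact mode) or
        "dense" (every location; linear mode only).
    """

    alpha: float = 1.0
    mode: str = "linear"
    patch_scheme: str = "dense"

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.mode not in ("exact", "linear"):
            raise ValueError("mode must be 'exact' or 'linear'")
        if self.patch_scheme not in ("tiling", "dense"):
            raise ValueError("patch_scheme must be 'tiling' or 'dense'")
        if self.mode == "exact" and self.patch_scheme != "tiling":
            raise ValueError("exact mode requires disjoint tiling")


def _weight_array(W) -> np.ndarray:
    return W.W if isinstance(W, LateralWeights) else np.asarray(W, float)


def contextual_inference_exact(c, W) -> ResponseMap:
    """Exact product-form surround integration on a tiled patch grid.

    ``c`` holds per-patch feature probabilities ``(K, Ph, Pw)`` on disjoint
    patches; ``W`` is indexed by *patch* offsets.  For each patch ``m``,

        f_j(m) ∝ c_j(m) * prod_{n != m} (1 + sum_k W[j,k,n-m] c_k(n)),

    normalized so the features sum to 1.  Bracket factors that go negative
    are floored at 0 (probabilities cannot be negative); if that zeroes
    every feature at a patch the patch falls back to the uniform vector
    with a warning.
    """
    vals = c.values if isinstance(c, ResponseMap) else np.asarray(c, float)
    Wd = _weight_array(W)
    K, Ph, Pw = vals.shape
    if Wd.shape[0] != K or Wd.shape[1] != K:
        raise ValueError("feature dimensions of c and W disagree")
    ry, rx = Wd.shape[2] // 2, Wd.shape[3] // 2

    out = np.empty_like(vals)
    for my in range(Ph):
        for mx in range(Pw):
            f = vals[:, my, mx].copy()
            for ny in range(max(0, my - ry), min(Ph, my + ry + 1)):
                for nx in range(max(0, mx - rx), min(Pw, mx + rx + 1)):
                    if (ny, nx) == (my, mx):
                        continue
                    bracket = 1.0 + Wd[:, :, ny - my + ry, nx - mx + rx] @ vals[:, ny, nx]
                    f *= np.maximum(bracket, 0.0)
            tot = f.sum()
            if tot <= 0.0:
                warnings.warn(
                    f"all features annihilated at patch ({my},{mx}); "
                    "using the uniform vector",
                    RuntimeWarning,
                )
                f = np.full(K, 1.0 / K)
            else:
                f /= tot
            out[:, my, mx] = f

    rm = ResponseMap(values=out, bank_ref=getattr(c, "bank_ref", ""))
    rm.validate()
    return rm


def surround_term(c, W, method: str = "auto") -> np.ndarray:
    """Surround drive S[j, m] = sum_k sum_{d != 0} W[j,k,d] c[k, m+d].

    Zero padding outside the map; the zero-offset entry of W is ignored.
    ``method``: "direct" (spatial correlation), "fft" (padded FFT), or
    "auto" (FFT for large kernel/feature counts).
    """
    vals = c.values if isinstance(c, ResponseMap) else np.asarray(c, float)
    Wd = _weight_array(W).copy()
    K, H, Wi = vals.shape
    if Wd.shape[:2] != (K, K):
        raise ValueError("feature dimensions of c and W disagree")
    ry, rx = Wd.shape[2] // 2, Wd.shape[3] // 2
    Wd[:, :, ry, rx] = 0.0  # surround only: n != m

    if method == "auto":
        method = "fft" if K * K * H * Wi * Wd.shape[2] * Wd.shape[3] > 2e7 else "direct"

    if method == "direct":
        S = np.zeros_like(vals, dtype=float)
        for j in range(K):
            for k in range(K):
                if not Wd[j, k].any():
                    continue
                S[j] += ndimage.correlate(
                    vals[k], Wd[j, k], mode="constant", cval=0.0
                )
        return S
    if method != "fft":
        raise ValueError("method must be 'auto', 'direct' or 'fft'")

    # correlation with kernel w == convolution with the flipped kernel;
    # pad so the circular product equals the zero-padded linear result
    PH, PW = H + 2 * ry, Wi + 2 * rx
    Fc = np.fft.rfft2(vals, s=(PH, PW))
    Fw = np.fft.rfft2(Wd[:, :, ::-1, ::-1], s=(PH, PW))
    FS = np.einsum("khw,jkhw->jhw", Fc, Fw)
    full = np.fft.irfft2(FS, s=(PH, PW))
    # alignment: flipped-kernel convolution shifts the map by +(ry, rx)
    return full[:, ry:ry + H, rx:rx + Wi]


def contextual_inference_linear(c, W, alpha: float) -> np.ndarray:
    """Linearized surround modulation ``f = c * (1 + alpha * S)``.

    ``c`` is any nonnegative feature map ``(K, H, W)``; no renormalization
    is applied (linear regime), and negative outputs are floored at 0.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    vals = c.values if isinstance(c, ResponseMap) else np.asarray(c, float)
    if alpha == 0:
        return vals.copy()
    S = surround_term(vals, W)
    return np.maximum(vals * (1.0 + alpha * S), 0.0)


def surround_effect_stats(responses, W) -> tuple[float, float]:
    """Mean and standard deviation of the surround term over a corpus.

    Pools ``S[j, m]`` (the linear form's surround drive before scaling by
    alpha) over every unit and every map.
    """
    terms = [surround_term(c, W).ravel() for c in responses]
    if not terms:
        raise ValueError("need at least one response map")
    allS = np.concatenate(terms)
    return float(allS.mean()), float(allS.std())
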