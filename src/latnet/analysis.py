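"""Orientation and distance dependence of lateral weights.

Summaries mirroring the connectivity analyses: mean connection strength as
a function of the difference in preferred orientation between the two
units (binned at 0/45/90 deg), ring-averaged weight profiles as a function
of Chebyshev distance on the offset grid, Gaussian fits to those profiles,
and the degrees-to-cortical-microns conversion via cortical magnification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .filterbank import FilterBank

__all__ = [
    "GaussianProfileFit",
    "orientation_dependence",
    "distance_profile",
    "fit_gaussian_profile",
    "sigma_to_microns",
]

ORI_BINS = (0.0, 45.0, 90.0)


@dataclass
class GaussianProfileFit:
    """Result of fitting ``w(r) = wm * exp(-r^2 / (2 sigma^2)) + w0``."""

    wm: float
    w0: float
    sigma: float
    rss: float
    degenerate: bool = False


def _component_tensor(W, tensor_shape=None) -> np.ndarray:
    arr = np.asarray(getattr(W, "W", W), dtype=float)
    if arr.ndim == 2:
        if tensor_shape is None:
            raise ValueError("matrix input requires tensor_shape")
        arr = arr.reshape(tensor_shape)
    if arr.ndim != 4:
        raise ValueError("expected a 4-D weight tensor")
    return arr


def _signed_part(arr: np.ndarray, sign: str) -> np.ndarray:
    if sign == "positive":
        return np.maximum(arr, 0.0)
    if sign == "negative":
        return np.abs(np.minimum(arr, 0.0))
    raise ValueError("sign must be 'positive' or 'negative'")


def orientation_dependence(
    W,
    bank: FilterBank,
    sign: str = "positive",
    tensor_shape=None,
) -> dict[float, float]:
    """Mean weight magnitude per orientation-difference bin.

    For every ordered pair of oriented filters the circular orientation
    difference ``min(|a-b|, 180-|a-b|)`` falls on one of {0, 45, 90} deg
    (the bank's orientations are multiples of 45 mod 180).  Returns the
    mean of the positive part (or |negative part|) of the weights over all
    pairs in a bin and all spatial offsets; unoriented filters are
    excluded.
    """
    arr = _signed_part(_component_tensor(W, tensor_shape), sign)
    ori = bank.preferred_orientation
    idx = np.flatnonzero(~np.isnan(ori))
    if idx.size == 0:
        raise ValueError("bank has no oriented filters")
    if arr.shape[0] != len(bank):
        raise ValueError("weight tensor and bank feature counts disagree")

    sums = {b: 0.0 for b in ORI_BINS}
    counts = {b: 0 for b in ORI_BINS}
    for j in idx:
        for k in idx:
            d = abs(ori[j] - ori[k]) % 180.0
            d = min(d, 180.0 - d)
            b = min(ORI_BINS, key=lambda x: abs(x - d))
            sums[b] += arr[j, k].sum()
            counts[b] += arr[j, k].size
    return {b: (sums[b] / counts[b] if counts[b] else np.nan) for b in ORI_BINS}


def distance_profile(
    W,
    sign: str = "positive",
    tensor_shape=None,
    rf_size: float | None = None,
) -> dict[str, np.ndarray]:
    """Ring-averaged weight profile vs Chebyshev distance.

    First the chosen signed part is averaged over all (target, source)
    feature pairs at each offset, then over the square ring
    ``max(|dy|, |dx|) = r`` for each integer ``r >= 1``.  Distances are
    returned both in raw pixels and, if ``rf_size`` is given, in
    receptive-field-size units (pixels / rf_size).
    """
    arr = _signed_part(_component_tensor(W, tensor_shape), sign)
    mean_map = arr.mean(axis=(0, 1))
    n = mean_map.shape[0]
    rmax = n // 2
    d = np.arange(-rmax, rmax + 1)
    cheb = np.maximum(np.abs(d)[:, None], np.abs(d)[None, :])

    rs = np.arange(1, rmax + 1)
    means = np.array([mean_map[cheb == r].mean() for r in rs])
    out = {"r_px": rs.astype(float), "mean_weight": means}
    if rf_size:
        out["r_rf"] = rs / float(rf_size)
    return out


def fit_gaussian_profile(
    r: np.ndarray,
    w: np.ndarray,
    max_nfev: int = 10000,
) -> GaussianProfileFit:
    """Nonlinear least-squares fit of a Gaussian-plus-offset profile.

    Initialization: ``wm = max - min``, ``w0 = min``, ``sigma`` = half the
    r-range.  A profile with (near-)zero fitted amplitude leaves sigma
    unidentifiable; the fit is then flagged degenerate.
    """
    r = np.asarray(r, float)
    w = np.asarray(w, float)
    if r.size < 4:
        raise ValueError("need at least 4 profile points")

    def model(x, wm, w0, sigma):
        return wm * np.exp(-(x**2) / (2.0 * sigma**2)) + w0

    p0 = (w.max() - w.min(), w.min(), 0.5 * (r.max() - r.min()))
    try:
        popt, _ = curve_fit(model, r, w, p0=p0, maxfev=max_nfev)
    except RuntimeError as err:
        raise RuntimeError(f"Gaussian profile fit did not converge: {err}") from err
    wm, w0, sigma = popt
    resid = w - model(r, *popt)
    rss = float(resid @ resid)
    scale = max(np.abs(w).max(), np.finfo(float).tiny)
    degenerate = abs(wm) < 1e-8 * scale or not np.isfinite(sigma)
    return GaussianProfileFit(
        wm=float(wm), w0=float(w0), sigma=float(abs(sigma)), rss=rss,
        degenerate=degenerate,
    )


def sigma_to_microns(sigma_deg: float, magnification_deg_per_mm: float = 30.0) -> float:
    """Convert a visual-field sigma (deg) to cortical distance (microns).

    Uses the cortical magnification factor (default 30 deg/mm):
    ``sigma_deg / magnification * 1000``.
    """
    if sigma_deg < 0 or magnification_deg_per_mm <= 0:
        raise ValueError("inputs must be positive (sigma may be zero)")
    return sigma_deg / magnification_deg_per_mm * 1000.0
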