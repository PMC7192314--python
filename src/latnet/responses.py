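"""Classical-receptive-field responses as feature probabilities.

An image is converted to grayscale, max-normalized, locally mean-subtracted
over each filter's support, correlated with each filter of a bank,
half-wave rectified, and divisively normalized across features at every
location so that the responses form a probability vector (they sum to one).
The normalized response ``c[k, y, x]`` is read as the probability that
feature ``k`` is present at location ``(y, x)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .filterbank import FilterBank

__all__ = ["ResponseMap", "preprocess_image", "crf_responses"]

_SUM_TOL = 1e-9


@dataclass
class ResponseMap:
    """Normalized feature responses of one image.

    Attributes
    ----------
    values : (n_features, H, W) ndarray
        Nonnegative responses summing to 1 over features at each location.
        ``(H, W)`` is the valid-correlation output size.
    origin : (int, int)
        0-based (row, col) image coordinate of the filter center at
        ``values[:, 0, 0]``.
    bank_ref : str
        Identifier of the filter bank used.
    """

    values: np.ndarray
    origin: tuple[int, int] = (0, 0)
    bank_ref: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    def validate(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("negative response values")
        sums = self.values.sum(axis=0)
        # all-zero columns are allowed only for the explicit zero-degenerate
        # mode; everything else must be a probability vector
        bad = (np.abs(sums - 1.0) > _SUM_TOL) & (sums != 0.0)
        if bad.any():
            raise ValueError("responses do not sum to 1 over features")


_LUMA = np.array([0.2989, 0.5870, 0.1140])


def preprocess_image(image: np.ndarray) -> np.ndarray:
    """Grayscale conversion and max-normalization.

    RGB(A) input is reduced with luma weights; the result is scaled so its
    maximum is 1 (an all-zero image is returned unchanged).  Local mean
    subtraction happens later, inside :func:`crf_responses`, over each
    filter's support.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if img.ndim == 3:
        if img.shape[2] not in (3, 4):
            raise ValueError(f"expected 3 or 4 channels, got {img.shape[2]}")
        img = img[:, :, :3] @ _LUMA
    elif img.ndim != 2:
        raise ValueError(f"expected 2-D or 3-D image, got ndim={img.ndim}")
    mx = img.max()
    if mx > 0:
        img = img / mx
    return img


def crf_responses(
    image: np.ndarray,
    bank: FilterBank,
    degenerate: str = "uniform",
    zero_atol: float = 1e-9,
) -> ResponseMap:
    """Compute normalized classical-RF responses of a preprocessed image.

    For each filter the image's local mean over the filter support is
    removed (so ON/OFF filters respond to contrast, not luminance), the
    mean-free patch is correlated with the filter (valid region only), the
    output is half-wave rectified, and at each location the feature vector
    is divided by its sum.  Locations where every rectified response is
    zero carry no evidence; they get the uniform vector 1/K by default
    (``degenerate="zero"`` leaves them at zero instead).  Raw responses
    with magnitude below ``zero_atol`` count as zero, so FFT round-off on
    evidence-free (e.g. constant) regions cannot masquerade as signal.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("crf_responses expects a 2-D preprocessed image")
    g = bank.grid_size
    if img.shape[0] < g or img.shape[1] < g:
        raise ValueError(
            f"image {img.shape} smaller than the {g}x{g} filter grid"
        )
    if degenerate not in ("uniform", "zero"):
        raise ValueError("degenerate must be 'uniform' or 'zero'")

    # local mean over the shared square support, valid region
    box = np.full((g, g), 1.0 / (g * g))
    local_mean = signal.fftconvolve(img, box, mode="valid")

    raw = np.empty((bank.n_filters,) + local_mean.shape)
    for i, kern in enumerate(bank.filters):
        # correlation = convolution with the flipped kernel; subtracting the
        # local mean is equivalent to correlating (img - mean) patchwise
        corr = signal.fftconvolve(img, kern[::-1, ::-1], mode="valid")
        raw[i] = corr - local_mean * kern.sum()

    raw[raw < zero_atol] = 0.0
    totals = raw.sum(axis=0)
    nz = totals > 0
    out = np.zeros_like(raw)
    out[:, nz] = raw[:, nz] / totals[nz]
    if degenerate == "uniform":
        out[:, ~nz] = 1.0 / bank.n_filters

    half = g // 2
    rm = ResponseMap(values=out, origin=(half, half), bank_ref=bank.name)
    rm.validate()
    return rm
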