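"""Seeded synthetic inputs for every stage of the pipeline.

Natural photographs and handwritten-digit scans are optional,
user-supplied inputs; these generators produce statistically controlled
stand-ins so the full pipeline runs self-contained:

- pink-noise images with a 1/f amplitude spectrum (the dominant
  second-order statistic of natural scenes);
- oriented-contour images whose collinear structure induces like-to-like
  feature co-occurrence;
- a binary feature process with a prescribed co-occurrence table, for
  which the expected lateral weights have a closed form;
- procedurally drawn 28x28 "toy digits" (stroke glyphs with jitter) as a
  classification fixture;
- ideal oriented edge stimuli.

Every generator is a pure function of its arguments (seed included).
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "gen_pink_noise_images",
    "gen_oriented_contours",
    "gen_binary_feature_process",
    "expected_binary_weights",
    "gen_toy_digits",
    "gen_edge_stimulus",
]


def _rescale01(img: np.ndarray) -> np.ndarray:
    lo, hi = img.min(), img.max()
    if hi > lo:
        return (img - lo) / (hi - lo)
    return np.zeros_like(img)


def gen_pink_noise_images(n: int, size: int = 128, seed: int = 0,
                          exponent: float = 1.0) -> np.ndarray:
    """Images with amplitude spectrum ~ 1/f^exponent, rescaled to [0, 1].

    Random Fourier phases with a radially symmetric 1/f amplitude
    envelope; the DC component is zeroed before rescaling.
    """
    rng = np.random.default_rng(seed)
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.rfftfreq(size)[None, :]
    f = np.hypot(fy, fx)
    amp = np.zeros_like(f)
    amp[f > 0] = 1.0 / f[f > 0] ** exponent
    out = np.empty((n, size, size))
    for i in range(n):
        phase = rng.uniform(0, 2 * math.pi, size=f.shape)
        spec = amp * np.exp(1j * phase)
        img = np.fft.irfft2(spec, s=(size, size))
        out[i] = _rescale01(img)
    return out


def _draw_segment(img: np.ndarray, y0: float, x0: float, theta: float,
                  length: float, amplitude: float, width: float) -> None:
    """Accumulate an anti-aliased straight stroke with a Gaussian profile."""
    size = img.shape[0]
    n_steps = max(int(2 * length), 2)
    t = np.linspace(0, length, n_steps)
    ys = y0 + t * math.sin(theta)
    xs = x0 + t * math.cos(theta)
    rad = max(int(3 * width), 1)
    for y, x in zip(ys, xs):
        iy, ix = int(round(y)), int(round(x))
        ylo, yhi = max(0, iy - rad), min(size, iy + rad + 1)
        xlo, xhi = max(0, ix - rad), min(size, ix + rad + 1)
        if ylo >= yhi or xlo >= xhi:
            continue
        yy, xx = np.mgrid[ylo:yhi, xlo:xhi]
        d2 = (yy - y) ** 2 + (xx - x) ** 2
        np.maximum(img[ylo:yhi, xlo:xhi],
                   amplitude * np.exp(-d2 / (2 * width**2)),
                   out=img[ylo:yhi, xlo:xhi])


def gen_oriented_contours(
    n: int,
    size: int = 96,
    seed: int = 0,
    n_contours: int = 6,
    segment_length: float = 18.0,
    collinear_prob: float = 0.9,
    n_segments: int = 3,
    orientations: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0),
    stroke_width: float = 1.2,
) -> np.ndarray:
    """Images of smooth oriented contours in [0, 1].

    Each contour is a chain of straight strokes; with probability
    ``collinear_prob`` a continuation keeps its predecessor's direction,
    otherwise it resamples one.  High collinearity makes same-orientation
    features co-occur at collinear offsets far beyond the filter size.
    """
    rng = np.random.default_rng(seed)
    out = np.zeros((n, size, size))
    for i in range(n):
        for _ in range(n_contours):
            theta = math.radians(rng.choice(orientations))
            y, x = rng.uniform(0, size, size=2)
            amp = rng.uniform(0.6, 1.0)
            for _seg in range(n_segments):
                _draw_segment(out[i], y, x, theta, segment_length, amp,
                              stroke_width)
                y += segment_length * math.sin(theta)
                x += segment_length * math.cos(theta)
                if rng.random() > collinear_prob:
                    theta = math.radians(rng.choice(orientations))
    return np.clip(out, 0.0, 1.0)


def gen_binary_feature_process(
    q: np.ndarray,
    P: np.ndarray,
    n_samples: int,
    seed: int = 0,
) -> list[np.ndarray]:
    """Binary feature maps realizing a prescribed co-occurrence table.

    Each sample is a (K, 1, 2) map: a site pair at horizontal offset
    ``dx = +1``.  The left site carries at most one feature, drawn with
    marginal probabilities ``q``; the right site is drawn conditionally so
    that ``Pr[c_j(left) = 1 and c_k(right) = 1] = P[j, k]`` while both
    sites keep marginals ``q``.  The expected lateral weight at that
    offset is then the closed form ``P[j,k] / (q[j] q[k]) - 1``
    (:func:`expected_binary_weights`).

    Requires sum(q) <= 1, P[j,k] <= q[j], column sums of P <= q (and the
    leftover conditional mass nonnegative); inconsistent tables are
    rejected.
    """
    q = np.asarray(q, float)
    P = np.asarray(P, float)
    K = q.size
    if P.shape != (K, K):
        raise ValueError("P must be K x K")
    if np.any(q <= 0) or q.sum() > 1 + 1e-12:
        raise ValueError("marginals must be positive with sum <= 1")
    if np.any(P < 0) or np.any(P > np.minimum(q[:, None], q[None, :]) + 1e-12):
        raise ValueError("P inconsistent with marginals (P_jk <= min(q_j, q_k))")
    colsum = P.sum(axis=0)
    q_none = 1.0 - q.sum()
    if np.any(colsum > q + 1e-12):
        raise ValueError("column sums of P exceed the marginals")
    if q_none > 0:
        r = (q - colsum) / q_none  # right-site law given an empty left site
        if np.any(r < -1e-12) or r.sum() > 1 + 1e-9:
            raise ValueError("(q, P) admit no consistent joint")
        r = np.clip(r, 0.0, None)
    else:
        if np.any(np.abs(colsum - q) > 1e-9):
            raise ValueError("(q, P) admit no consistent joint")
        r = np.zeros(K)

    rng = np.random.default_rng(seed)
    # left-site category: feature j with prob q_j, else empty
    left_p = np.append(q, q_none)
    cond = np.empty((K + 1, K + 1))
    for j in range(K):
        row = P[j] / q[j]
        cond[j, :K] = row
        cond[j, K] = 1.0 - row.sum()
    cond[K, :K] = r
    cond[K, K] = 1.0 - r.sum()
    if np.any(cond < -1e-9):
        raise ValueError("(q, P) admit no consistent joint")
    cond = np.clip(cond, 0.0, None)
    cond /= cond.sum(axis=1, keepdims=True)

    lefts = rng.choice(K + 1, size=n_samples, p=left_p / left_p.sum())
    rights = np.empty(n_samples, dtype=np.int64)
    for l in range(K + 1):
        sel = lefts == l
        rights[sel] = rng.choice(K + 1, size=int(sel.sum()), p=cond[l])
    maps = []
    for l, rgt in zip(lefts, rights):
        m = np.zeros((K, 1, 2))
        if l < K:
            m[l, 0, 0] = 1.0
        if rgt < K:
            m[rgt, 0, 1] = 1.0
        maps.append(m)
    return maps


def expected_binary_weights(q: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Closed-form lateral weight P_jk / (q_j q_k) - 1 at the pair offset."""
    q = np.asarray(q, float)
    return np.asarray(P, float) / (q[:, None] * q[None, :]) - 1.0


# ----------------------------------------------------------------- toy digits

# stroke endpoints in a unit box (y, x), per glyph class
_GLYPH_STROKES = {
    0: [((0.15, 0.25), (0.15, 0.75)), ((0.15, 0.75), (0.85, 0.75)),
        ((0.85, 0.75), (0.85, 0.25)), ((0.85, 0.25), (0.15, 0.25))],  # box
    1: [((0.1, 0.5), (0.9, 0.5))],                                    # vertical
    2: [((0.5, 0.1), (0.5, 0.9))],                                    # horizontal
    3: [((0.1, 0.1), (0.9, 0.9)), ((0.1, 0.9), (0.9, 0.1))],          # X
    4: [((0.1, 0.5), (0.9, 0.5)), ((0.5, 0.1), (0.5, 0.9))],          # plus
    5: [((0.1, 0.2), (0.9, 0.2)), ((0.9, 0.2), (0.9, 0.8))],          # L
    6: [((0.1, 0.2), (0.1, 0.8)), ((0.1, 0.2), (0.9, 0.2)),
        ((0.1, 0.8), (0.9, 0.8))],                                    # U (open)
    7: [((0.1, 0.1), (0.1, 0.9)), ((0.1, 0.9), (0.9, 0.1))],          # 7-like
    8: [((0.1, 0.1), (0.9, 0.9))],                                    # diagonal
    9: [((0.5, 0.5), (0.5, 0.5)), ((0.15, 0.5), (0.5, 0.85)),
        ((0.5, 0.85), (0.85, 0.5)), ((0.85, 0.5), (0.5, 0.15)),
        ((0.5, 0.15), (0.15, 0.5))],                                  # diamond
}


def gen_toy_digits(
    n: int,
    n_classes: int = 4,
    size: int = 28,
    seed: int = 0,
    jitter: float = 1.5,
    width_range: tuple[float, float] = (0.9, 1.4),
) -> tuple[np.ndarray, np.ndarray]:
    """Procedurally drawn stroke glyphs: a handwritten-digit stand-in.

    Returns ``(images, labels)`` with balanced classes, images in [0, 1]
    of shape (n, size, size).  Each glyph's stroke endpoints are jittered
    (pixels) and its stroke width and amplitude vary per sample, so
    classes are separable but not trivial.  At most 10 classes.
    """
    if not 2 <= n_classes <= 10:
        raise ValueError("n_classes must be between 2 and 10")
    rng = np.random.default_rng(seed)
    labels = np.arange(n) % n_classes
    rng.shuffle(labels)
    images = np.zeros((n, size, size))
    scale = size * 0.85
    off = size * 0.075
    for i, lab in enumerate(labels):
        width = rng.uniform(*width_range)
        amp = rng.uniform(0.75, 1.0)
        dy, dx = rng.uniform(-1.5, 1.5, size=2)
        for (y0, x0), (y1, x1) in _GLYPH_STROKES[int(lab)]:
            jy0, jx0, jy1, jx1 = rng.uniform(-jitter, jitter, size=4)
            ay, ax = y0 * scale + off + dy + jy0, x0 * scale + off + dx + jx0
            by, bx = y1 * scale + off + dy + jy1, x1 * scale + off + dx + jx1
            length = math.hypot(by - ay, bx - ax)
            theta = math.atan2(by - ay, bx - ax)
            _draw_segment(images[i], ay, ax, theta, max(length, 1.0), amp, width)
    return np.clip(images, 0.0, 1.0), labels.astype(np.int64)


def gen_edge_stimulus(size: int = 64, orientation: float = 0.0,
                      contrast: float = 1.0, smooth: float = 1.0) -> np.ndarray:
    """An ideal light/dark edge at the given orientation (deg), in [0, 1].

    The edge passes through the image center; ``orientation`` is the
    direction along the edge, so 0 deg is a horizontal edge (dark above,
    light below).  ``smooth`` is the sigmoid width in pixels.
    """
    half = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size] - half
    rad = math.radians(orientation)
    # signed distance from the edge line (normal direction)
    d = yy * math.cos(rad) - xx * math.sin(rad)
    img = 0.5 + 0.5 * contrast * np.tanh(d / max(smooth, 1e-6))
    return np.clip(img, 0.0, 1.0)
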