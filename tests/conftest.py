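import numpy as np
import pytest

import latnet as ln
from latnet.synthetic import gen_oriented_contours


@pytest.fixture(scope="session")
def bank():
    return ln.build_v1_basis()


@pytest.fixture(scope="session")
def contour_maps(bank):
    """Responses of the default bank to collinear oriented-contour images."""
    imgs = gen_oriented_contours(20, size=96, seed=7)
    return [ln.crf_responses(ln.preprocess_image(im), bank) for im in imgs]


@pytest.fixture(scope="session")
def contour_weights(contour_maps):
    """Lateral weights learned from the contour corpus (full 43x43 grid)."""
    return ln.cooccurrence_weights(contour_maps, max_offset=21)


def naive_cooccurrence(maps, max_offset):
    """Double-loop reference implementation of the co-occurrence weights."""
    r = max_offset
    K = maps[0].shape[0]
    n = 2 * r + 1
    num = np.zeros((K, K, n, n))
    cnt = np.zeros((n, n))
    tot = np.zeros(K)
    npos = 0
    for v in maps:
        _, H, W = v.shape
        tot += v.sum(axis=(1, 2))
        npos += H * W
        for my in range(H):
            for mx in range(W):
                for dy in range(-r, r + 1):
                    for dx in range(-r, r + 1):
                        ny, nx = my + dy, mx + dx
                        if 0 <= ny < H and 0 <= nx < W:
                            num[:, :, dy + r, dx + r] += np.outer(
                                v[:, my, mx], v[:, ny, nx])
                            cnt[dy + r, dx + r] += 1
    means = tot / npos
    return num / cnt / np.outer(means, means)[:, :, None, None] - 1.0
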