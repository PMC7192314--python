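"""Low-rank + column-sparse decomposition of lateral weight matrices.

The lateral weight tensor, flattened to a matrix ``G`` (rows: target
feature; columns: source feature x spatial offset), is split as
``G = L + S`` by an adaptive robust PCA — a weighted principal component
pursuit

    min ||L||_* + ||Lambda S||_1   s.t.   G = L + S,

solved by an inexact augmented-Lagrangian scheme alternating singular-value
thresholding (L) with column-weighted soft thresholding (S).  The diagonal
weight ``Lambda_ii`` adapts each outer iteration to the l1 mass of column
``i`` of S, so columns that become active are penalized less, which drives
S toward column sparsity.

The low-rank part is then truncated by SVD to the rank retaining a target
fraction of variance and split, together with S, into signed components:
``W_LR+`` (disynaptic excitation), ``W_S+`` (direct excitation), ``W_LR-``
and ``W_S-`` (low-rank and sparse disynaptic inhibition) — the labels the
model attaches to interneuron-mediated pathways.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .lateral import LateralWeights

__all__ = [
    "RPCAConfig",
    "WeightDecomposition",
    "matricize",
    "dematricize",
    "adaptive_rpca",
    "split_components",
    "decompose_weights",
]

_SPARSITY_ATOL = 1e-12

#: interpretive labels for the four signed components
COMPONENT_LABELS = {
    "W_LR_pos": "disynaptic Pyr-Pyr",
    "W_S_pos": "direct Pyr-Pyr",
    "W_S_neg": "sparse inhibition",
    "W_LR_neg": "lowrank inhibition",
}


@dataclass(frozen=True)
class RPCAConfig:
    """Adaptive-RPCA solver settings.

    beta : trade-off between low-rank and sparse terms (default 0.01, the
        value used for the image-statistics weight matrix).
    gamma : adaptation speed of the column weights (default 1.0).
    tol : relative reconstruction tolerance ||G-L-S||_F / ||G||_F.
    max_iter : outer-iteration cap.
    variance_retained : fraction of squared singular values kept when
        truncating L.
    adaptive_rule : "ratio" uses Lambda_ii = beta / (||S_i||_1 + gamma);
        "literal" uses beta * ||S_i||_1 + gamma.
    """

    beta: float = 0.01
    gamma: float = 1.0
    tol: float = 1e-7
    max_iter: int = 500
    variance_retained: float = 0.99
    adaptive_rule: str = "ratio"

    def __post_init__(self) -> None:
        if self.beta <= 0 or self.gamma <= 0:
            raise ValueError("beta and gamma must be positive")
        if not 0 < self.variance_retained <= 1:
            raise ValueError("variance_retained must be in (0, 1]")
        if self.adaptive_rule not in ("ratio", "literal"):
            raise ValueError("adaptive_rule must be 'ratio' or 'literal'")


@dataclass
class WeightDecomposition:
    """Signed low-rank/sparse components of a weight matrix."""

    L: np.ndarray
    S: np.ndarray
    W_LR_pos: np.ndarray
    W_LR_neg: np.ndarray
    W_S_pos: np.ndarray
    W_S_neg: np.ndarray
    singular_values: np.ndarray
    retained_rank: int
    sparsity_entries: float
    sparsity_columns: float
    converged: bool
    n_iter: int
    residual: float
    labels: dict = field(default_factory=lambda: dict(COMPONENT_LABELS))
    tensor_shape: tuple | None = None

    def component(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def validate(self, G: np.ndarray | None = None, tol: float = 1e-6) -> None:
        if np.any(self.W_LR_pos < 0) or np.any(self.W_S_pos < 0):
            raise ValueError("positive component has negative entries")
        if np.any(self.W_LR_neg > 0) or np.any(self.W_S_neg > 0):
            raise ValueError("negative component has positive entries")
        if not np.allclose(self.W_S_pos + self.W_S_neg, self.S, atol=1e-10):
            raise ValueError("S split does not reassemble S")
        if G is not None:
            denom = max(np.linalg.norm(G), np.finfo(float).tiny)
            if np.linalg.norm(G - self.L - self.S) / denom > tol:
                raise ValueError("L + S does not reconstruct G within tol")


def matricize(lw: LateralWeights | np.ndarray) -> np.ndarray:
    """Flatten a (J, K, Oy, Ox) weight tensor to (J, K*Oy*Ox).

    Columns are ordered source-feature-major, then offset row (dy), then
    offset column (dx) — i.e. C-order flattening of the trailing three
    axes.  :func:`dematricize` inverts this exactly.
    """
    W = lw.W if isinstance(lw, LateralWeights) else np.asarray(lw)
    if W.ndim != 4:
        raise ValueError("expected a 4-D weight tensor")
    return W.reshape(W.shape[0], -1)


def dematricize(M: np.ndarray, tensor_shape: tuple) -> np.ndarray:
    """Restore the 4-D tensor from its matricization."""
    return np.asarray(M).reshape(tensor_shape)


def _svt(X: np.ndarray, tau: float) -> tuple[np.ndarray, np.ndarray]:
    """Singular-value thresholding prox of the nuclear norm."""
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    s_thr = np.maximum(s - tau, 0.0)
    return (U * s_thr) @ Vt, s_thr


def adaptive_rpca(G: np.ndarray, cfg: RPCAConfig | None = None) -> tuple[np.ndarray, np.ndarray, dict]:
    """Split ``G`` into low-rank ``L`` and column-sparse ``S``.

    Inexact augmented Lagrangian iteration: each sweep applies
    singular-value thresholding at 1/mu to ``G - S + Y/mu``, soft
    thresholding at ``Lambda_i / mu`` columnwise to ``G - L + Y/mu``, a
    dual update ``Y += mu (G - L - S)``, and growth ``mu *= 1.5``; the
    column weights ``Lambda`` are re-adapted from S each sweep.  Returns
    ``(L, S, info)`` where ``info`` records convergence diagnostics; a
    run that hits ``max_iter`` is returned with a warning flag rather
    than raised.
    """
    cfg = cfg or RPCAConfig()
    G = np.asarray(G, dtype=float)
    if not np.all(np.isfinite(G)):
        raise ValueError("G contains non-finite entries")
    if G.ndim != 2:
        raise ValueError("G must be a matrix")

    normG = np.linalg.norm(G)
    if normG == 0.0:
        return np.zeros_like(G), np.zeros_like(G), {
            "converged": True, "n_iter": 0, "residual": 0.0,
            "lambda": np.full(G.shape[1], cfg.beta / cfg.gamma),
        }

    spec = np.linalg.norm(G, 2)
    mu = 1.25 / spec
    rho = 1.5
    L = np.zeros_like(G)
    S = np.zeros_like(G)
    Y = G / max(spec, np.linalg.norm(G, np.inf))  # standard dual init
    lam = np.full(G.shape[1], _lambda_rule(np.zeros(G.shape[1]), cfg))

    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        L, _ = _svt(G - S + Y / mu, 1.0 / mu)
        R = G - L + Y / mu
        S = np.sign(R) * np.maximum(np.abs(R) - lam[None, :] / mu, 0.0)
        Z = G - L - S
        Y = Y + mu * Z
        mu *= rho
        lam = _lambda_rule(np.abs(S).sum(axis=0), cfg)
        residual = np.linalg.norm(Z) / normG
        if residual <= cfg.tol:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"adaptive RPCA did not converge in {cfg.max_iter} iterations "
            f"(residual {residual:.2e})",
            RuntimeWarning,
        )
    info = {"converged": converged, "n_iter": it, "residual": float(residual),
            "lambda": lam}
    return L, S, info


def _lambda_rule(col_l1: np.ndarray, cfg: RPCAConfig) -> np.ndarray:
    if cfg.adaptive_rule == "ratio":
        return cfg.beta / (col_l1 + cfg.gamma)
    return cfg.beta * col_l1 + cfg.gamma


def objective(L: np.ndarray, S: np.ndarray, lam: np.ndarray) -> float:
    """Weighted PCP objective ||L||_* + ||Lambda S||_1."""
    return float(np.linalg.svd(L, compute_uv=False).sum()
                 + (lam[None, :] * np.abs(S)).sum())


def split_components(
    L: np.ndarray,
    S: np.ndarray,
    variance_retained: float = 0.99,
    info: dict | None = None,
    G: np.ndarray | None = None,
    tensor_shape: tuple | None = None,
) -> WeightDecomposition:
    """Truncate L by variance and split L and S into signed components.

    The SVD of L is cut at the smallest rank whose cumulative squared
    singular values reach ``variance_retained``.  Each retained rank-1 term
    ``sigma u v^T`` contributes ``sigma (u+ v+^T + u- v-^T)`` to the
    positive low-rank component and ``sigma (u+ v-^T + u- v+^T)`` to the
    negative one, so the two sum back to the truncated L.  S splits
    entrywise.
    """
    U, s, Vt = np.linalg.svd(L, full_matrices=False)
    if s.sum() == 0:
        rank = 0
    else:
        cum = np.cumsum(s**2) / np.sum(s**2)
        rank = int(np.searchsorted(cum, variance_retained - 1e-12) + 1)
    U, s_r, Vt = U[:, :rank], s[:rank], Vt[:rank]
    V = Vt.T

    Up, Un = np.maximum(U, 0.0), np.minimum(U, 0.0)
    Vp, Vn = np.maximum(V, 0.0), np.minimum(V, 0.0)
    W_LR_pos = (Up * s_r) @ Vp.T + (Un * s_r) @ Vn.T
    W_LR_neg = (Up * s_r) @ Vn.T + (Un * s_r) @ Vp.T

    W_S_pos = np.maximum(S, 0.0)
    W_S_neg = np.minimum(S, 0.0)

    ref = G if G is not None else L + S
    ref_nz = np.abs(ref) > _SPARSITY_ATOL
    s_nz = np.abs(S) > _SPARSITY_ATOL
    n_ref = max(int(ref_nz.sum()), 1)
    sparsity_entries = float(s_nz.sum()) / n_ref
    col_ref = max(int(np.any(ref_nz, axis=0).sum()), 1)
    sparsity_columns = float(np.any(s_nz, axis=0).sum()) / col_ref

    dec = WeightDecomposition(
        L=L, S=S,
        W_LR_pos=W_LR_pos, W_LR_neg=W_LR_neg,
        W_S_pos=W_S_pos, W_S_neg=W_S_neg,
        singular_values=s,
        retained_rank=rank,
        sparsity_entries=sparsity_entries,
        sparsity_columns=sparsity_columns,
        converged=bool(info["converged"]) if info else True,
        n_iter=int(info["n_iter"]) if info else 0,
        residual=float(info["residual"]) if info else 0.0,
        tensor_shape=tensor_shape,
    )
    dec.validate(G=G)
    return dec


def decompose_weights(
    lw: LateralWeights,
    cfg: RPCAConfig | None = None,
) -> WeightDecomposition:
    """End-to-end: matricize, adaptive RPCA, signed component split."""
    cfg = cfg or RPCAConfig()
    G = matricize(lw)
    L, S, info = adaptive_rpca(G, cfg)
    return split_components(
        L, S, cfg.variance_retained, info=info, G=G,
        tensor_shape=lw.W.shape,
    )
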