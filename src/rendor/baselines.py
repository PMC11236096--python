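"""Comparator network denoisers.

Four established methods for separating direct from indirect
dependencies in a similarity or interaction matrix, used as baselines
against reverse network diffusion:

- :func:`nd_denoise` — network deconvolution: eigenvalue reweighting
  ``lambda -> lambda / (1 + lambda)``, which inverts the geometric
  transitive-closure series ``G_dir + G_dir^2 + ...``.
- :func:`ne_denoise` — network enhancement: a doubly-stochastic-style
  diffusion on a KNN-localised kernel.
- :func:`silencer_denoise` — perturbation-response "silencing" of
  indirect correlations, ``S = (C - I + D((C - I) C)) C^{-1}``.
- :func:`icm_denoise` — inverse correlation matrix / partial
  correlation from the precision matrix.

All functions take and return dense ``numpy`` arrays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

logger = logging.getLogger(__name__)

__all__ = [
    "NEConfig",
    "nd_denoise",
    "ne_denoise",
    "silencer_denoise",
    "icm_denoise",
    "adjacency_to_correlation",
    "score_to_ranking_adapter",
]

_COND_LIMIT = 1e12


@dataclass(frozen=True)
class NEConfig:
    """Network-enhancement hyper-parameters.

    ``k`` nearest neighbours define each node's local neighbourhood
    (default ``min(20, n - 1)`` when left as None), ``alpha`` is the
    retained fraction of diffused signal in each update, and
    ``iterations`` the number of diffusion updates.
    """

    k: int | None = None
    alpha: float = 0.9
    iterations: int = 2

    def resolve_k(self, n: int) -> int:
        k = min(20, n - 1) if self.k is None else self.k
        if not 1 <= k < n:
            raise ValueError(f"neighbourhood size k={k} must satisfy 1 <= k < n={n}")
        return k

    def __post_init__(self) -> None:
        if not 0 <= self.alpha < 1:
            raise ValueError(f"alpha must be in [0, 1), got {self.alpha}")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


def _check_symmetric(M, name: str = "matrix", tol: float = 1e-10) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be square, got shape {M.shape}")
    if not np.allclose(M, M.T, atol=tol):
        raise ValueError(f"{name} must be symmetric within {tol}")
    return M


def _nd_scale_factor(eigvals: np.ndarray, scale: float) -> float:
    """Linear rescaling delta so that after the eigenvalue map
    ``lambda -> lambda/(1 + lambda)`` all mapped values lie in
    ``(-scale, scale]`` with the extreme mapped value equal to ``scale``."""
    lam_max = float(eigvals.max())
    lam_min = float(eigvals.min())
    candidates = []
    if lam_max > 0:
        candidates.append(scale / (lam_max * (1.0 - scale)))
    if lam_min < 0:
        candidates.append(scale / (abs(lam_min) * (1.0 + scale)))
    return min(candidates) if candidates else 1.0


def nd_denoise(G, scale: float | None = 0.9) -> np.ndarray:
    """Network deconvolution via eigenvalue reweighting.

    The observed similarity matrix is modelled as the transitive closure
    ``G_obs = G_dir + G_dir^2 + ... = G_dir (I - G_dir)^{-1}``, which in a
    shared eigenbasis amounts to ``lambda_obs = lambda_dir/(1-lambda_dir)``.
    Deconvolution inverts this per eigenvalue:
    ``lambda_dir = lambda_obs / (1 + lambda_obs)``.

    ``scale`` linearly rescales the input so every reweighted eigenvalue
    lies in ``(-1, 1)`` with the extreme one equal to ``scale`` (spectral
    radius of the output below 1); pass ``scale=None`` to apply the raw
    eigenvalue map without rescaling.
    """
    G = _check_symmetric(G, "similarity matrix")
    lam, U = np.linalg.eigh(G)
    if scale is not None:
        if not 0 < scale < 1:
            raise ValueError(f"scale must be in (0, 1), got {scale}")
        lam = _nd_scale_factor(lam, scale) * lam
    if np.any(np.abs(1.0 + lam) < 1e-12):
        raise np.linalg.LinAlgError(
            "eigenvalue at -1 after rescaling; deconvolution map is singular"
        )
    lam_dir = lam / (1.0 + lam)
    out = (U * lam_dir) @ U.T
    return 0.5 * (out + out.T)


def _ne_kernels(W: np.ndarray, k: int) -> np.ndarray:
    """Build NE's localised transition kernel T from W.

    ``P[i, j] = W[i, j] / sum_{l in N_i} W[i, l]`` for j in the k nearest
    (largest-weight) neighbours of i, zero elsewhere;
    ``T[i, j] = sum_l P[i, l] P[j, l] / sum_v P[v, l]``.
    """
    n = W.shape[0]
    P = np.zeros_like(W)
    for i in range(n):
        w = W[i].copy()
        w[i] = 0.0
        order = np.argsort(-w, kind="stable")
        nbrs = [j for j in order[:k] if w[j] > 0]
        if 0 < len(nbrs) < k:
            logger.info("node %d has only %d positive-weight neighbours (k=%d)",
                        i, len(nbrs), k)
        if not nbrs:
            continue
        P[i, nbrs] = w[nbrs] / w[nbrs].sum()
    col = P.sum(axis=0)
    col[col == 0] = 1.0  # empty columns contribute nothing
    return (P / col) @ P.T


def ne_denoise(W, cfg: NEConfig | None = None) -> np.ndarray:
    """Network enhancement: diffusion on a KNN-localised kernel.

    Iterates ``W_{t+1} = alpha * T W_t T + (1 - alpha) * T`` from the
    input matrix, where T encodes each node's k-nearest-neighbour local
    structure; the update amplifies weights supported by their local
    neighbourhoods and damps isolated (likely spurious) edges.
    """
    W = _check_symmetric(np.asarray(W, dtype=float), "weight matrix", tol=1e-8)
    if np.any(W < 0):
        raise ValueError("network enhancement expects nonnegative weights")
    cfg = cfg or NEConfig()
    k = cfg.resolve_k(W.shape[0])
    T = _ne_kernels(W, k)
    Wt = W.copy()
    for _ in range(cfg.iterations):
        Wt = cfg.alpha * (T @ Wt @ T) + (1.0 - cfg.alpha) * T
    return 0.5 * (Wt + Wt.T)


def _checked_inverse(C: np.ndarray, ridge: float | None, method: str) -> np.ndarray:
    if ridge is not None:
        if ridge <= 0:
            raise ValueError("ridge must be positive")
        logger.warning("%s: applying ridge regularisation C + %.3g I", method, ridge)
        C = C + ridge * np.eye(C.shape[0])
    cond = np.linalg.cond(C)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise np.linalg.LinAlgError(
            f"{method}: input matrix is singular or ill-conditioned "
            f"(cond ~ {cond:.3g}); pass ridge=<delta> (e.g. 1e-6) to "
            f"regularise explicitly"
        )
    return scipy.linalg.inv(C)


def silencer_denoise(C, *, ridge: float | None = None, symmetrize: bool = True) -> np.ndarray:
    """Silencing of indirect correlation effects.

    Treats the correlation matrix C as a global response containing both
    direct and indirect contributions and solves for the local response
    ``S = (C - I + D((C - I) C)) C^{-1}``, where ``D(X)`` zeroes the
    off-diagonal of X.  Singular C raises; pass ``ridge`` to opt in to
    explicit regularisation ``C + ridge * I``.  ``symmetrize=False``
    returns the raw (slightly asymmetric) solution of the defining
    equation, useful for residual checks.
    """
    C = _check_symmetric(C, "correlation matrix")
    if not np.allclose(np.diag(C), 1.0, atol=1e-8):
        raise ValueError("silencer expects a correlation matrix with unit diagonal")
    n = C.shape[0]
    I = np.eye(n)
    Cinv = _checked_inverse(C, ridge, "silencer")
    if ridge is not None:
        C = C + ridge * I
    inner = (C - I) @ C
    S = (C - I + np.diag(np.diag(inner))) @ Cinv
    return 0.5 * (S + S.T) if symmetrize else S


def icm_denoise(C, *, ridge: float | None = None) -> np.ndarray:
    """Partial correlations from the inverse correlation (precision) matrix.

    ``S = C^{-1}``; off-diagonal output is
    ``-S_ij / sqrt(S_ii S_jj)`` (the partial correlation of i and j given
    all other variables) and the diagonal is 1.
    """
    C = _check_symmetric(C, "correlation matrix")
    S = _checked_inverse(C, ridge, "icm")
    d = np.sqrt(np.diag(S))
    if np.any(~np.isfinite(d)) or np.any(d <= 0):
        raise np.linalg.LinAlgError("precision matrix has non-positive diagonal")
    P = -S / np.outer(d, d)
    P = 0.5 * (P + P.T)
    np.fill_diagonal(P, 1.0)
    return P


def adjacency_to_correlation(W) -> np.ndarray:
    """Embed a weighted adjacency matrix as a correlation-like matrix.

    The silencer and partial-correlation baselines expect a symmetric
    positive-definite matrix with unit diagonal, whereas simulated noisy
    networks are plain (often binary) adjacencies.  Scaling by one over
    the spectral radius plus one, ``C = W / (rho(W) + 1) + I``, keeps all
    eigenvalues strictly positive (the smallest is at least
    ``1 - rho/(rho + 1) > 0``) while preserving the off-diagonal ranking.
    """
    W = _check_symmetric(W, "weight matrix", tol=1e-8)
    rho = float(np.max(np.abs(np.linalg.eigvalsh(W))))
    if rho == 0:
        return np.eye(W.shape[0])
    return W / (rho + 1.0) + np.eye(W.shape[0])


def score_to_ranking_adapter(M, node_ids=None, *, absolute: bool = True):
    """Flatten a symmetric score matrix into a ranked edge list.

    Emits one ``(node_a, node_b, score)`` triple per unordered pair
    ``i < j``.  Signed outputs (silencer, partial correlation) are ranked
    by magnitude by default, since evaluation concerns edge existence,
    not sign.  See :func:`rendor.metrics.matrix_to_ranking`.
    """
    from .metrics import matrix_to_ranking

    return matrix_to_ranking(M, node_ids=node_ids, absolute=absolute)
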