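"""Random-walk diffusion operators on weighted undirected graphs.

This module implements the forward network-diffusion operator ``f_m`` and
its exact functional inverse ``f_m^{-1}`` acting on row-stochastic
transition matrices, the graph/walk mappings ``g`` (graph to random walk)
and ``h`` (random walk back to graph via the stationary distribution), and
the composite denoiser that chains them:

    preprocess -> g -> inverse diffusion -> negative-row correction -> h

Forward diffusion mixes a transition matrix with the probabilities of all
longer paths, each path of length ``k`` discounted by ``1/m**k``; it has the
closed form ``(m - 1) P (m I - P)^{-1}``.  Inverting that operator,
``m ((m - 1) I + P)^{-1} P``, strips the accumulated indirect (transitive)
contributions of paths of every length at once, which is the denoising
principle behind reverse network diffusion.

All operators work on plain ``numpy`` arrays; node labels are handled at
the I/O layer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Union

import numpy as np
import scipy.linalg

__all__ = [
    "DenoiseConfig",
    "to_transition",
    "forward_diffusion",
    "inverse_diffusion",
    "stationary",
    "from_transition",
    "preprocess",
    "clip_negative_rows",
    "rendor_denoise",
    "nr_diffuse",
]

#: sentinel for "pick epsilon from the data" in :func:`preprocess`
AUTO = "auto"
#: sentinel for "scale output to the input's total weight" in the denoisers
MATCH_INPUT_SUM = "match-input-sum"

_ROW_SUM_TOL = 1e-8
_NEG_TOL = 1e-12


@dataclass(frozen=True)
class DenoiseConfig:
    """Hyper-parameters of the reverse-diffusion denoiser.

    Parameters
    ----------
    m
        Diffusion intensity; the decay base for path length.  Must be
        strictly greater than 1 so the path series converges.  Larger ``m``
        discounts long paths more heavily and denoises more gently.
        Default 4.
    eps1, eps2
        Preprocessing offsets added to every entry (``eps1``) and to the
        diagonal (``eps2``) before denoising; they make the walk
        irreducible and tame negative entries produced by the inverse
        operator.  The string ``"auto"`` picks 1 for unweighted graphs and
        the minimum nonzero weight otherwise.
    alpha
        Output weight scale of the walk-to-graph mapping ``h``.  The
        default sentinel matches the output's total weight to the
        preprocessed input's total weight; rankings do not depend on it.
    renormalize_rows
        After the per-row negative-value correction, rescale each row to
        sum to one before computing the stationary distribution (default).
        If False, the corrected matrix is used as-is and ``h`` uses its
        dominant left eigenvector.
    random_seed
        Unused by the deterministic operators; carried for provenance.
    """

    m: float = 4.0
    eps1: Union[float, str] = AUTO
    eps2: Union[float, str] = AUTO
    alpha: Union[float, str] = MATCH_INPUT_SUM
    renormalize_rows: bool = True
    random_seed: Union[int, None] = None

    def __post_init__(self) -> None:
        if not self.m > 1:
            raise ValueError(
                f"diffusion intensity m must be > 1 for the path series to "
                f"converge; got m={self.m}"
            )


def _as_square_array(M, name: str = "matrix") -> np.ndarray:
    A = np.asarray(M, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"{name} must be square 2-D, got shape {A.shape}")
    if A.shape[0] < 2:
        raise ValueError(f"{name} must have at least 2 nodes")
    return A


def _check_weight_matrix(W, *, allow_diagonal: bool = False) -> np.ndarray:
    W = _as_square_array(W, "weight matrix")
    if np.any(W < 0):
        i, j = np.argwhere(W < 0)[0]
        raise ValueError(f"weight matrix has negative entry at ({i}, {j})")
    if not np.allclose(W, W.T, atol=1e-8):
        raise ValueError("weight matrix must be symmetric (undirected graph)")
    if not allow_diagonal and np.any(np.abs(np.diag(W)) > 1e-12):
        raise ValueError("weight matrix must have zero diagonal (no self-loops)")
    return W


def _check_transition(P, *, nonnegative: bool = True) -> np.ndarray:
    P = _as_square_array(P, "transition matrix")
    rs = P.sum(axis=1)
    if not np.allclose(rs, 1.0, atol=_ROW_SUM_TOL):
        bad = int(np.argmax(np.abs(rs - 1.0)))
        raise ValueError(
            f"matrix is not row-stochastic: row {bad} sums to {rs[bad]:.6g}"
        )
    if nonnegative and np.any(P < -_NEG_TOL):
        i, j = np.argwhere(P < -_NEG_TOL)[0]
        raise ValueError(f"transition matrix has negative entry at ({i}, {j})")
    return P


def _check_m(m: float) -> float:
    m = float(m)
    if not m > 1:
        raise ValueError(f"m must be > 1 (series convergence); got {m}")
    return m


def to_transition(W) -> np.ndarray:
    """Map a weighted graph to its random walk: ``g(W) = D^{-1} W``.

    Each row is divided by the node's (weighted) degree, giving the
    row-stochastic transition matrix of the random walk on the graph.

    Raises
    ------
    ValueError
        If some node has zero degree (no outgoing probability mass);
        preprocessing with positive offsets removes this failure mode.
    """
    W = _check_weight_matrix(W, allow_diagonal=True)
    deg = W.sum(axis=1)
    zero = np.flatnonzero(deg <= 0)
    if zero.size:
        raise ValueError(
            f"node(s) {zero.tolist()} have zero degree; the random walk is "
            f"undefined there (preprocess with eps1, eps2 > 0 first)"
        )
    return W / deg[:, None]


def forward_diffusion(P, m: float = 4.0) -> np.ndarray:
    """Forward diffusion ``f_m(P) = (m - 1) P (m I - P)^{-1}``.

    Equals the normalised path series
    ``sum_{k>=1} P^k / m^k  /  sum_{k>=1} 1/m^k``: the walk is blended with
    the probability of every longer path, discounted geometrically in path
    length.  The result is again row-stochastic.
    """
    m = _check_m(m)
    P = _check_transition(P, nonnegative=False)
    n = P.shape[0]
    A = m * np.eye(n) - P
    try:
        # right-multiplication by A^{-1}: solve A^T X^T = P^T
        out = scipy.linalg.solve(A.T, P.T).T
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(
            f"(m I - P) is numerically singular (cond ~ {np.linalg.cond(A):.3g}); "
            f"this should not happen for row-stochastic P and m > 1"
        ) from exc
    return (m - 1.0) * out


def inverse_diffusion(P, m: float = 4.0) -> np.ndarray:
    """Inverse diffusion ``f_m^{-1}(P) = m ((m - 1) I + P)^{-1} P``.

    Exact functional inverse of :func:`forward_diffusion`: it removes the
    indirect contributions of paths of all lengths in one step.  Rows of
    the result sum to one, but entries may be negative when the input walk
    was not actually generated by forward diffusion (sparse graphs); see
    :func:`clip_negative_rows`.
    """
    m = _check_m(m)
    P = _check_transition(P, nonnegative=False)
    n = P.shape[0]
    A = (m - 1.0) * np.eye(n) + P
    try:
        out = scipy.linalg.solve(A, P)
    except scipy.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"((m - 1) I + P) is numerically singular "
            f"(cond ~ {np.linalg.cond(A):.3g})"
        ) from exc
    return m * out


def stationary(P, *, tol: float = 1e-12, maxiter: int = 100_000) -> np.ndarray:
    """Stationary distribution pi of a transition matrix: ``pi P = pi``.

    Dense left eigen-decomposition is used up to 2000 nodes, power
    iteration above.  The chain must be irreducible (guaranteed for walks
    on preprocessed graphs, which are complete); a reducible chain has no
    unique stationary distribution and raises.
    """
    P = _check_transition(P)
    n = P.shape[0]
    if n <= 2000:
        vals, vecs = scipy.linalg.eig(P, left=True, right=False)
        close = np.flatnonzero(np.abs(vals - 1.0) < 1e-8)
        if close.size == 0:
            raise np.linalg.LinAlgError(
                "no unit eigenvalue found; matrix is not a valid transition matrix"
            )
        if close.size > 1:
            raise ValueError(
                "transition matrix is reducible (unit eigenvalue is not simple); "
                "preprocess the graph with eps1 > 0 to make the walk irreducible"
            )
        pi = np.real(vecs[:, close[0]])
    else:
        pi = np.full(n, 1.0 / n)
        for _ in range(maxiter):
            nxt = pi @ P
            if np.max(np.abs(nxt - pi)) < tol:
                pi = nxt
                break
            pi = nxt
        else:
            raise RuntimeError(
                f"power iteration did not converge in {maxiter} iterations"
            )
    pi = pi / pi.sum()
    if np.any(pi < -1e-8):
        raise ValueError(
            "left principal eigenvector has negative entries; the chain "
            "appears reducible or the matrix is not stochastic"
        )
    pi = np.clip(pi, 0.0, None)
    pi = pi / pi.sum()
    resid = np.max(np.abs(pi @ P - pi))
    if resid > 1e-8:
        raise RuntimeError(f"stationary distribution residual {resid:.3g} > 1e-8")
    return pi


def _left_principal(P) -> np.ndarray:
    """Dominant left eigenvector (sum normalised to 1) without the
    stochasticity checks; used for the literal, non-renormalised pipeline
    where row sums deviate from one after the negative-row correction."""
    P = _as_square_array(P)
    vals, vecs = scipy.linalg.eig(P, left=True, right=False)
    i = int(np.argmax(np.abs(vals)))
    v = np.real(vecs[:, i])
    if v.sum() < 0:
        v = -v
    return v / v.sum()


def from_transition(
    P,
    alpha: float = 1.0,
    *,
    zero_diagonal: bool = True,
    _pi: np.ndarray | None = None,
) -> np.ndarray:
    """Map a random walk back to a graph: ``h(P) = alpha * diag(pi) P``.

    The transition probability out of each node is reweighted by the
    node's stationary mass, restoring degree information.  For a
    non-reversible chain ``diag(pi) P`` is slightly asymmetric, so the
    result is symmetrised as ``(M + M^T)/2``; by default the diagonal is
    zeroed as well, since self-loops are not meaningful edges in the
    undirected-network domain (``zero_diagonal=False`` keeps the
    self-loop mass, which makes forward diffusion exactly invertible at
    the graph level).  ``alpha`` only rescales and never changes edge
    rankings.
    """
    pi = stationary(P) if _pi is None else _pi
    M = alpha * (pi[:, None] * np.asarray(P, dtype=float))
    M = 0.5 * (M + M.T)
    if zero_diagonal:
        np.fill_diagonal(M, 0.0)
    return M


def preprocess(W, eps1: Union[float, str] = AUTO, eps2: Union[float, str] = AUTO) -> np.ndarray:
    """Offset a weight matrix: ``W~ = W + eps1 * J + eps2 * I``.

    ``J`` is the all-ones matrix.  The offsets make the graph complete
    (hence the walk irreducible) and counteract negative entries in the
    inverse-diffusion step.  With ``"auto"``, both offsets are 1 for an
    unweighted graph (all nonzero weights equal) and the minimum nonzero
    weight for a weighted graph, so the offsets never dominate real edges.
    """
    W = _check_weight_matrix(W, allow_diagonal=True)
    if isinstance(eps1, str) or isinstance(eps2, str):
        if not (eps1 == AUTO and eps2 == AUTO):
            raise ValueError(f"epsilon must be a number >= 0 or '{AUTO}'")
        nz = W[W > 0]
        if nz.size == 0:
            auto = 1.0
        elif np.all(np.abs(nz - 1.0) < 1e-12):
            auto = 1.0  # unweighted graph
        elif np.all(np.abs(nz - nz[0]) < 1e-12):
            auto = 1.0  # constant-weight graph is unweighted up to scale
        else:
            auto = float(nz.min())
        eps1 = eps2 = auto
    if eps1 < 0 or eps2 < 0:
        raise ValueError(f"epsilon offsets must be >= 0, got ({eps1}, {eps2})")
    n = W.shape[0]
    return W + eps1 * np.ones((n, n)) + eps2 * np.eye(n)


def clip_negative_rows(P, *, neg_tol: float = _NEG_TOL) -> np.ndarray:
    """Remove negative entries row-wise by shifting.

    For each row whose minimum is negative (below ``-neg_tol``, so tiny
    floating-point negatives are left alone), the row minimum is
    subtracted from every entry of that row; rows without negative
    entries are unchanged.  This is the correction applied when inverse
    diffusion is run on a network that was not literally generated by
    forward diffusion.
    """
    P = _as_square_array(P)
    row_min = P.min(axis=1)
    beta = np.where(row_min < -neg_tol, row_min, 0.0)
    return P - beta[:, None]


def _resolve_alpha(alpha, M_unit: np.ndarray, target_sum: float) -> float:
    if isinstance(alpha, str):
        if alpha != MATCH_INPUT_SUM:
            raise ValueError(f"alpha must be a positive number or '{MATCH_INPUT_SUM}'")
        total = M_unit.sum()
        if total <= 0:
            raise ValueError("cannot match input sum: output has no weight")
        return target_sum / total
    alpha = float(alpha)
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    return alpha


def rendor_denoise(W, cfg: DenoiseConfig | None = None, **overrides) -> np.ndarray:
    """Reverse-diffusion denoising of a weighted undirected network.

    Pipeline (composite operator ``h . f_m^{-1} . g`` with pre/post
    correction):

    1. offset the weights (:func:`preprocess`) so the walk is irreducible,
    2. form the random walk (:func:`to_transition`),
    3. apply inverse diffusion (:func:`inverse_diffusion`) to strip
       indirect path contributions of every length,
    4. shift away negative rows (:func:`clip_negative_rows`) and, by
       default, renormalise rows back to probability,
    5. map the walk back to a graph (:func:`from_transition`).

    Returns a dense symmetric matrix with zero diagonal: pairs absent
    from the input may acquire a small weight, and true edges inflated by
    transitive effects are deflated.  Deterministic for fixed input and
    configuration.

    Parameters can be given as a :class:`DenoiseConfig` or as keyword
    overrides (``m=``, ``eps1=``, ``eps2=``, ``alpha=``,
    ``renormalize_rows=``).
    """
    cfg = replace(cfg or DenoiseConfig(), **overrides)
    W = _check_weight_matrix(W, allow_diagonal=True)

    Wt = preprocess(W, cfg.eps1, cfg.eps2)
    P_obs = to_transition(Wt)
    P_dir = inverse_diffusion(P_obs, cfg.m)
    P_dir = clip_negative_rows(P_dir)
    if cfg.renormalize_rows:
        P_dir = P_dir / P_dir.sum(axis=1)[:, None]
        M = from_transition(P_dir, alpha=1.0)
    else:
        M = from_transition(P_dir, alpha=1.0, _pi=_left_principal(P_dir))

    off_diag_target = Wt.sum() - np.trace(Wt)
    return _resolve_alpha(cfg.alpha, M, off_diag_target) * M


def nr_diffuse(W, cfg: DenoiseConfig | None = None, **overrides) -> np.ndarray:
    """Forward network diffusion ``h . f_m . g`` on a graph.

    The generative counterpart of :func:`rendor_denoise`: it spreads each
    edge's weight along paths of all lengths (discounted by ``1/m**k``),
    producing the kind of transitively-inflated network the denoiser is
    designed to invert.  No preprocessing offsets are applied, so the
    input must be connected with no zero-degree node.  Self-loop mass
    created by even-length return paths is kept in the output (the
    diffused network genuinely carries it, and dropping it would make the
    operator non-invertible).  Shares the alpha scaling convention with
    the denoiser.
    """
    cfg = replace(cfg or DenoiseConfig(), **overrides)
    W = _check_weight_matrix(W, allow_diagonal=True)
    P = to_transition(W)
    P_out = forward_diffusion(P, cfg.m)
    M = from_transition(P_out, alpha=1.0, zero_diagonal=False)
    return _resolve_alpha(cfg.alpha, M, W.sum()) * M
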