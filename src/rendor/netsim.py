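"""Simulated ground-truth networks with injected indirect-noise edges.

True networks are drawn from three classical topologies — a cycle
("circular"), Erdős–Rényi G(n, p), and Barabási–Albert preferential
attachment — and then corrupted by adding spurious edges between
non-adjacent node pairs.  Noise placement mimics the transitive
mechanism that plagues inferred gene regulatory networks: the more
short paths already connect two nodes, the more likely a spurious edge
appears between them.  Every edge in the noisy network carries a label
(``signal`` for true edges, ``noise`` for injected ones) so downstream
evaluation is exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Tuple

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "NoisySimSpec",
    "LabeledNetwork",
    "make_true_graph",
    "inject_indirect_noise",
    "noise_sweep",
]

TOPOLOGIES = ("circular", "er", "ba")

Pair = Tuple[int, int]


@dataclass(frozen=True)
class NoisySimSpec:
    """Parameters of one simulated noisy network.

    ``noise_proportion`` is the fraction of edges in the *noisy* network
    that are injected noise (swept over 0.1–0.5 in the benchmark);
    ``decay`` is the base of the geometric path-length discount used to
    score candidate noise positions, and ``max_path_len`` the longest
    path length contributing to that score.
    """

    topology: str = "er"
    n: int = 50
    p: float = 0.3  # ER edge-formation probability
    e: int = 3  # BA edges added per new node
    noise_proportion: float = 0.3
    decay: float = 4.0
    seed: int = 0
    max_path_len: int = 4
    kernel: str = "path_count"  # or "diffusion"

    def __post_init__(self) -> None:
        if self.kernel not in ("path_count", "diffusion"):
            raise ValueError(f"unknown noise kernel {self.kernel!r}")
        if self.topology not in TOPOLOGIES:
            raise ValueError(
                f"unknown topology {self.topology!r}; expected one of {TOPOLOGIES}"
            )
        if self.n < 3:
            raise ValueError("need at least 3 nodes")
        if self.topology == "er" and not 0 < self.p < 1:
            raise ValueError(f"ER probability p must be in (0, 1), got {self.p}")
        if self.topology == "ba" and not 1 <= self.e < self.n:
            raise ValueError(f"BA e must satisfy 1 <= e < n, got e={self.e}")
        if not 0 < self.noise_proportion < 1:
            raise ValueError("noise_proportion must be in (0, 1)")
        if not self.decay > 1:
            raise ValueError("decay must be > 1")


@dataclass
class LabeledNetwork:
    """A noisy network with per-edge ground-truth labels.

    ``labels`` maps each positive-weight unordered pair ``(i, j)`` with
    ``i < j`` to ``"signal"`` (edge of the true network) or ``"noise"``
    (injected indirect edge); pairs absent from the map carry no edge.
    """

    weights: np.ndarray
    labels: Dict[Pair, str]
    spec: NoisySimSpec = field(repr=False)

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def signal_pairs(self) -> set:
        return {p for p, lab in self.labels.items() if lab == "signal"}

    def noise_pairs(self) -> set:
        return {p for p, lab in self.labels.items() if lab == "noise"}


def make_true_graph(spec: NoisySimSpec) -> np.ndarray:
    """Sample the ground-truth adjacency matrix for a simulation spec.

    ``circular`` is the deterministic n-cycle; ``er`` draws each of the
    C(n, 2) pairs independently with probability p; ``ba`` grows a
    preferential-attachment graph adding ``e`` edges per new node.
    Disconnected draws (possible only for ER) are regenerated with an
    incremented seed so the random-graph model itself is untouched.
    """
    seed = spec.seed
    for attempt in range(1000):
        if spec.topology == "circular":
            G = nx.cycle_graph(spec.n)
        elif spec.topology == "er":
            G = nx.gnp_random_graph(spec.n, spec.p, seed=seed + attempt)
        else:  # ba
            G = nx.barabasi_albert_graph(spec.n, spec.e, seed=seed + attempt)
        if nx.is_connected(G):
            if attempt:
                logger.info("regenerated %s graph %d time(s) for connectivity",
                            spec.topology, attempt)
            break
    else:  # pragma: no cover - p would have to be tiny
        raise RuntimeError(
            f"could not draw a connected {spec.topology} graph in 1000 attempts"
        )
    return nx.to_numpy_array(G, nodelist=range(spec.n), dtype=float)


def _noise_scores(A: np.ndarray, decay: float, max_len: int) -> np.ndarray:
    """Path-proximity score for candidate noise positions.

    ``s_ij = sum_{k=2}^{K} (A^k)_ij / decay^k`` over non-adjacent pairs:
    many short paths between i and j give a high score, mirroring how
    transitive effects create spurious edges.
    """
    s = np.zeros_like(A)
    Ak = A.copy()
    for k in range(2, max_len + 1):
        Ak = Ak @ A
        s += Ak / decay**k
    s[A > 0] = 0.0
    np.fill_diagonal(s, 0.0)
    return s


def _diffusion_scores(W_true: np.ndarray, decay: float) -> np.ndarray:
    """Alternative noise kernel: score non-edges by the weight the forward
    diffusion operator itself assigns them, i.e. place noise exactly where
    the transitive mechanism the denoiser inverts would put it."""
    from .diffusion import nr_diffuse

    s = nr_diffuse(W_true, m=decay)
    s[W_true > 0] = 0.0
    np.fill_diagonal(s, 0.0)
    return s


def noise_edge_quota(n_true_edges: int, noise_proportion: float) -> int:
    """Number of noise edges so they form ``noise_proportion`` of the
    noisy network: ``round(q / (1 - q) * |E_true|)``."""
    return int(round(noise_proportion / (1.0 - noise_proportion) * n_true_edges))


def inject_indirect_noise(
    W_true: np.ndarray,
    spec: NoisySimSpec,
    rng: np.random.Generator | None = None,
) -> LabeledNetwork:
    """Add path-proximity-weighted spurious edges to a true network.

    Candidate positions are the non-adjacent pairs; each is scored by a
    length-discounted count of existing paths joining it and the quota of
    noise edges is sampled without replacement with probability
    proportional to that score.  Zero-score pairs are only used (drawn
    uniformly, with a log notice) if the quota cannot otherwise be met.
    Injected edges get the mean weight of the existing edges, so
    unweighted graphs stay unweighted.
    """
    W_true = np.asarray(W_true, dtype=float)
    n = W_true.shape[0]
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    iu, ju = np.triu_indices(n, k=1)
    on_edge = W_true[iu, ju] > 0
    n_true = int(on_edge.sum())
    quota = noise_edge_quota(n_true, spec.noise_proportion)
    free = ~on_edge
    if quota > int(free.sum()):
        max_prop = free.sum() / (free.sum() + n_true)
        raise ValueError(
            f"requested {quota} noise edges but only {int(free.sum())} "
            f"non-edges exist; maximum achievable noise proportion is "
            f"{max_prop:.3f}"
        )

    labels: Dict[Pair, str] = {
        (int(i), int(j)): "signal" for i, j in zip(iu[on_edge], ju[on_edge])
    }
    W = W_true.copy()
    if quota > 0:
        A = (W_true > 0).astype(float)
        if spec.kernel == "diffusion":
            scores = _diffusion_scores(W_true, spec.decay)[iu, ju]
        else:
            scores = _noise_scores(A, spec.decay, spec.max_path_len)[iu, ju]
        scores[~free] = 0.0
        cand = np.flatnonzero(free & (scores > 0))
        if cand.size >= quota:
            p = scores[cand] / scores[cand].sum()
            chosen = rng.choice(cand, size=quota, replace=False, p=p)
        else:
            logger.warning(
                "only %d positively-scored non-edges for a quota of %d; "
                "filling the rest uniformly", cand.size, quota,
            )
            rest = np.flatnonzero(free & (scores == 0))
            extra = rng.choice(rest, size=quota - cand.size, replace=False)
            chosen = np.concatenate([cand, extra])
        w_noise = float(W_true[W_true > 0].mean()) if n_true else 1.0
        for idx in chosen:
            i, j = int(iu[idx]), int(ju[idx])
            W[i, j] = W[j, i] = w_noise
            labels[(i, j)] = "noise"
    return LabeledNetwork(weights=W, labels=labels, spec=spec)


def make_noisy_network(spec: NoisySimSpec) -> LabeledNetwork:
    """Convenience: sample the true graph and inject noise in one call."""
    W_true = make_true_graph(spec)
    return inject_indirect_noise(W_true, spec)


def noise_sweep(
    spec_base: NoisySimSpec,
    proportions: List[float],
    replicates: int = 20,
) -> List[LabeledNetwork]:
    """Generate replicate noisy networks over a grid of noise proportions.

    Seeds are derived deterministically as
    ``base_seed + 1000 * proportion_index + replicate_index`` so any cell
    of the sweep can be regenerated in isolation.
    """
    if not proportions:
        raise ValueError("proportions must be nonempty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    out: List[LabeledNetwork] = []
    for pi, prop in enumerate(proportions):
        for ri in range(replicates):
            spec = replace(
                spec_base,
                noise_proportion=prop,
                seed=spec_base.seed + 1000 * pi + ri,
            )
            out.append(make_noisy_network(spec))
    return out
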