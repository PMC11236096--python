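"""Edge-ranking evaluation of denoised networks.

A denoised network is judged by how well its edge weights rank the true
(direct) edges above everything else — injected noise edges and absent
pairs alike — over the universe of all C(n, 2) unordered node pairs.
Metrics: AUROC in the Mann–Whitney formulation (ties count one half),
AUPR as the step-wise non-interpolated area (average precision),
confusion counts when the top-k edges are kept, and the TP-versus-k
retention curve.  :func:`benchmark` runs a panel of denoisers over
simulated noisy networks and aggregates scores per noise level.
"""

from __future__ import annotations

from typing import Callable, Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score

from .netsim import LabeledNetwork

__all__ = [
    "matrix_to_ranking",
    "truth_vector",
    "auroc",
    "aupr",
    "confusion_at_k",
    "tp_curve",
    "benchmark",
    "default_method_panel",
]

Pair = Tuple


def matrix_to_ranking(M, node_ids=None, *, absolute: bool = True) -> pd.DataFrame:
    """Flatten a symmetric score matrix to one row per unordered pair.

    Returns a DataFrame with columns ``node_a``, ``node_b``, ``score``
    covering every pair ``i < j``.  Signed scores are ranked by magnitude
    when ``absolute`` is set, since the evaluation target is edge
    existence rather than sign.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {M.shape}")
    if not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("expected a symmetric score matrix")
    n = M.shape[0]
    ids = list(range(n)) if node_ids is None else list(node_ids)
    if len(ids) != n:
        raise ValueError(f"{len(ids)} node ids for a {n}-node matrix")
    iu, ju = np.triu_indices(n, k=1)
    scores = M[iu, ju]
    if absolute:
        scores = np.abs(scores)
    return pd.DataFrame(
        {
            "node_a": [ids[i] for i in iu],
            "node_b": [ids[j] for j in ju],
            "score": scores,
        }
    )


def _norm_pair(a, b) -> Pair:
    return (a, b) if a <= b else (b, a)


def truth_vector(ranking: pd.DataFrame, truth) -> np.ndarray:
    """Align ground truth with a ranking.

    ``truth`` is either a mapping from unordered pair to {0, 1} or a set
    of positive pairs; returns the 0/1 label vector in ranking order.
    """
    if isinstance(truth, Mapping):
        def lab(p):
            return int(truth.get(p, 0))
    else:
        pos = {_norm_pair(*p) for p in truth}

        def lab(p):
            return int(p in pos)

    return np.array(
        [lab(_norm_pair(a, b)) for a, b in zip(ranking["node_a"], ranking["node_b"])],
        dtype=int,
    )


def _check_labels(y: np.ndarray, need_negative: bool = True) -> None:
    if y.sum() == 0:
        raise ValueError("no positive labels; metric undefined")
    if need_negative and y.sum() == len(y):
        raise ValueError("no negative labels; metric undefined")


def auroc(ranking: pd.DataFrame, truth) -> float:
    """Area under the ROC curve, Mann–Whitney formulation.

    The probability that a uniformly drawn positive pair scores above a
    uniformly drawn negative pair, with tied scores counted one half.
    """
    y = truth_vector(ranking, truth)
    _check_labels(y)
    s = ranking["score"].to_numpy(dtype=float)
    r = rankdata(s)  # mid-ranks handle ties at 1/2
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    u = r[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def aupr(ranking: pd.DataFrame, truth) -> float:
    """Area under the precision–recall curve.

    Step-wise non-interpolated area over descending score thresholds
    (average precision), the standard convention in network-inference
    benchmarking.
    """
    y = truth_vector(ranking, truth)
    _check_labels(y, need_negative=False)
    return float(average_precision_score(y, ranking["score"].to_numpy(dtype=float)))


def _top_k_mask(ranking: pd.DataFrame, k: int) -> np.ndarray:
    """Boolean mask of the k highest-scored pairs; ties broken by
    lexicographic (node_a, node_b) order for determinism."""
    n = len(ranking)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    order = sorted(
        range(n),
        key=lambda i: (
            -ranking["score"].iat[i],
            ranking["node_a"].iat[i],
            ranking["node_b"].iat[i],
        ),
    )
    mask = np.zeros(n, dtype=bool)
    mask[order[:k]] = True
    return mask


def confusion_at_k(ranking: pd.DataFrame, truth, k: int) -> Dict[str, int]:
    """Confusion counts when exactly the top-k pairs are called edges.

    Returns ``{"tp", "fp", "tn", "fn"}``; ``tp + fp == k`` and
    ``tp + fn`` equals the number of positive labels.
    """
    y = truth_vector(ranking, truth)
    pred = _top_k_mask(ranking, k)
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    return {"tp": tp, "fp": fp, "tn": tn, "fn": fn}


def f1_at_k(ranking: pd.DataFrame, truth, k: int) -> float:
    c = confusion_at_k(ranking, truth, k)
    denom = 2 * c["tp"] + c["fp"] + c["fn"]
    return 0.0 if denom == 0 else 2.0 * c["tp"] / denom


def tp_curve(ranking: pd.DataFrame, truth, ks: Sequence[int]) -> List[Tuple[int, int]]:
    """True-positive count as a function of how many top edges are kept.

    ``ks`` must be ascending; the curve is nondecreasing in k.
    """
    ks = list(ks)
    if ks != sorted(ks):
        raise ValueError("ks must be sorted ascending")
    return [(k, confusion_at_k(ranking, truth, k)["tp"]) for k in ks]


def _evaluate_one(scores, network: LabeledNetwork) -> Tuple[float, float]:
    ranking = matrix_to_ranking(scores)
    truth = network.signal_pairs()
    return auroc(ranking, truth), aupr(ranking, truth)


def benchmark(
    methods: Mapping[str, Callable[[np.ndarray], np.ndarray]],
    networks: Iterable[LabeledNetwork],
    *,
    include_input: bool = True,
) -> pd.DataFrame:
    """Score a panel of denoisers on labelled noisy networks.

    ``methods`` maps a method name to a callable taking the noisy weight
    matrix and returning a symmetric score matrix.  Per method, topology
    and noise proportion, the mean and standard deviation of AUROC and
    AUPR over replicates are reported; the undenoised input is included
    as the ``input`` baseline.  A method failure on one network is
    recorded as NaN for that cell rather than aborting the run.

    Returns a tidy DataFrame with columns
    ``method, topology, proportion, metric, mean, sd, replicates``.
    """
    if not methods:
        raise ValueError("methods must be nonempty")
    methods = dict(methods)
    if include_input and "input" not in methods:
        methods = {"input": lambda W: W, **methods}

    rows: List[dict] = []
    for net in networks:
        for name, fn in methods.items():
            try:
                scores = fn(net.weights)
                roc, pr = _evaluate_one(scores, net)
            except Exception as exc:  # recorded, not fatal
                import logging

                logging.getLogger(__name__).warning(
                    "method %r failed on %s(prop=%.2f, seed=%d): %s",
                    name, net.spec.topology, net.spec.noise_proportion,
                    net.spec.seed, exc,
                )
                roc = pr = float("nan")
            rows.append(
                {
                    "method": name,
                    "topology": net.spec.topology,
                    "proportion": net.spec.noise_proportion,
                    "auroc": roc,
                    "aupr": pr,
                }
            )
    raw = pd.DataFrame(rows)
    long = raw.melt(
        id_vars=["method", "topology", "proportion"],
        value_vars=["auroc", "aupr"],
        var_name="metric",
    )
    out = (
        long.groupby(["method", "topology", "proportion", "metric"])["value"]
        .agg(mean="mean", sd="std", replicates="count")
        .reset_index()
    )
    out["sd"] = out["sd"].fillna(0.0)
    return out


def default_method_panel(
    m: float = 4.0,
    *,
    nd_scale: float = 0.9,
    ne_cfg=None,
) -> Dict[str, Callable[[np.ndarray], np.ndarray]]:
    """The five-denoiser panel used throughout the simulation benchmark.

    Reverse diffusion and network enhancement consume the weight matrix
    directly; network deconvolution consumes it as a similarity matrix;
    the silencer and partial-correlation methods consume the
    positive-definite correlation embedding of
    :func:`rendor.baselines.adjacency_to_correlation`.  Signed outputs
    are ranked by magnitude downstream.
    """
    from .baselines import (
        NEConfig,
        adjacency_to_correlation,
        icm_denoise,
        nd_denoise,
        ne_denoise,
        silencer_denoise,
    )
    from .diffusion import rendor_denoise

    ne_cfg = ne_cfg or NEConfig()
    return {
        "rendor": lambda W: rendor_denoise(W, m=m),
        "nd": lambda W: nd_denoise(W, scale=nd_scale),
        "ne": lambda W: ne_denoise(W, ne_cfg),
        "silencer": lambda W: silencer_denoise(adjacency_to_correlation(W)),
        "icm": lambda W: icm_denoise(adjacency_to_correlation(W)),
    }
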