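"""Reading and writing networks as plain-text files.

Supported formats:

- ``edge_list_tsv`` — three tab-separated columns ``node_a  node_b
  weight`` (header optional, auto-detected; a missing weight column
  defaults to 1.0 for unweighted graphs).
- ``adjacency_tsv`` — a dense matrix with node ids as the first row and
  column.
- ``dream_gold_tsv`` — gold-standard edge lists ``regulator  target
  {0,1}``; directed pairs are symmetrised since the denoisers operate on
  undirected networks.

Node identifiers are opaque strings (gene symbols in practice); matrices
carry an explicit id order, preserved on output.  All writes are atomic
(temp file then rename) and each output is accompanied by a YAML sidecar
recording the configuration that produced it.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import yaml

from .netsim import LabeledNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "read_network",
    "write_network",
    "read_gold_standard",
    "read_edge_labels",
    "write_labeled_network",
    "pad_to_square",
]


@dataclass
class Network:
    """A square symmetric weight matrix with its node labels."""

    values: np.ndarray
    node_ids: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not self.node_ids:
            self.node_ids = [str(i) for i in range(self.values.shape[0])]
        if len(self.node_ids) != self.values.shape[0]:
            raise ValueError("node_ids length does not match matrix size")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _atomic_write(path: Path, text: str) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or Path("."), suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_sidecar(path, config: dict) -> None:
    """Record the exact run configuration next to an output file."""
    from . import __version__

    doc = {"rendor_version": __version__, **config}
    _atomic_write(Path(str(path) + ".run.yaml"), yaml.safe_dump(doc, sort_keys=False))


def _detect_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return "edge_list_tsv" if len(line.rstrip("\n").split("\t")) <= 3 else "adjacency_tsv"
    raise ValueError(f"{path}: empty file")


def _has_header(first_fields: Sequence[str]) -> bool:
    if len(first_fields) < 3:
        return False
    try:
        float(first_fields[2])
        return False
    except ValueError:
        return True


def _read_edge_list(path: Path, default_weight: float = 1.0) -> Network:
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip() and not l.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: no edges")
    rows = [l.split("\t") for l in lines]
    if _has_header(rows[0]):
        rows = rows[1:]

    node_ids: List[str] = []
    index: Dict[str, int] = {}

    def idx(name: str) -> int:
        if name not in index:
            index[name] = len(node_ids)
            node_ids.append(name)
        return index[name]

    edges: Dict[Tuple[int, int], float] = {}
    for lineno, r in enumerate(rows, start=1):
        if len(r) < 2:
            raise ValueError(f"{path}:{lineno}: expected at least 2 columns")
        a, b = idx(r[0]), idx(r[1])
        w = float(r[2]) if len(r) > 2 and r[2] != "" else default_weight
        if w < 0:
            raise ValueError(f"{path}:{lineno}: negative weight {w}")
        if a == b:
            raise ValueError(f"{path}:{lineno}: self-loop on {r[0]}")
        key = (min(a, b), max(a, b))
        if key in edges:
            if abs(edges[key] - w) > 1e-12:
                raise ValueError(
                    f"{path}:{lineno}: duplicate edge {r[0]}-{r[1]} with "
                    f"conflicting weights {edges[key]} and {w}"
                )
            logger.warning("%s:%d: duplicate edge %s-%s (same weight, kept once)",
                           path, lineno, r[0], r[1])
        edges[key] = w

    n = len(node_ids)
    W = np.zeros((n, n))
    for (a, b), w in edges.items():
        W[a, b] = W[b, a] = w
    return Network(W, node_ids)


def _read_adjacency(path: Path, symmetrize: bool = False) -> Network:
    first = pd.read_csv(path, sep="\t", header=None, nrows=1)
    labelled = first.iloc[0].map(lambda v: isinstance(v, str)).any()
    if labelled:
        df = pd.read_csv(path, sep="\t", index_col=0)
        node_ids = [str(c) for c in df.columns]
    else:
        df = pd.read_csv(path, sep="\t", header=None)
        node_ids = [str(i) for i in range(df.shape[1])]
    W = df.to_numpy(dtype=float)
    if W.shape[0] != W.shape[1]:
        raise ValueError(f"{path}: adjacency matrix is {W.shape}, not square")
    if np.any(W < 0):
        raise ValueError(f"{path}: negative weights in adjacency matrix")
    if not np.allclose(W, W.T, atol=1e-8):
        if not symmetrize:
            raise ValueError(
                f"{path}: adjacency matrix is asymmetric beyond 1e-8; "
                f"pass symmetrize to average the two directions"
            )
        W = 0.5 * (W + W.T)
    return Network(W, node_ids)


def read_network(
    path,
    fmt: str = "auto",
    *,
    symmetrize: bool = False,
    default_weight: float = 1.0,
) -> Network:
    """Read a network file into a :class:`Network`.

    ``fmt`` is one of ``auto``, ``edge_list_tsv``, ``adjacency_tsv``;
    ``auto`` decides by column count of the first data line.  Node order
    is first appearance (edge lists) or header order (adjacency).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "auto":
        fmt = _detect_format(path)
    if fmt == "edge_list_tsv":
        return _read_edge_list(path, default_weight)
    if fmt == "adjacency_tsv":
        return _read_adjacency(path, symmetrize)
    raise ValueError(f"unknown network format {fmt!r}")


def write_network(net: Network, path, fmt: str = "edge_list_tsv", *, config: dict | None = None) -> None:
    """Write a network atomically; optionally record a config sidecar.

    Edge lists contain the positive-weight pairs (i < j in node order);
    adjacency output is the full labelled matrix.
    """
    path = Path(path)
    if fmt == "edge_list_tsv":
        lines = ["node_a\tnode_b\tweight"]
        n = net.n
        for i in range(n):
            for j in range(i + 1, n):
                w = net.values[i, j]
                if w > 0:
                    lines.append(f"{net.node_ids[i]}\t{net.node_ids[j]}\t{w:.10g}")
        _atomic_write(path, "\n".join(lines) + "\n")
    elif fmt == "adjacency_tsv":
        df = pd.DataFrame(net.values, index=net.node_ids, columns=net.node_ids)
        _atomic_write(path, df.to_csv(sep="\t"))
    else:
        raise ValueError(f"unknown network format {fmt!r}")
    if config is not None:
        write_sidecar(path, config)


def read_gold_standard(path) -> Set[Tuple[str, str]]:
    """Read a DREAM-style gold standard (regulator, target, {0,1}).

    Directed pairs are symmetrised; returns the set of positive
    unordered pairs.
    """
    pos: Set[Tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            if f[2] not in ("0", "1"):
                raise ValueError(f"{path}:{lineno}: label must be 0 or 1, got {f[2]!r}")
            if f[2] == "1":
                a, b = sorted((f[0], f[1]))
                pos.add((a, b))
    return pos


def read_edge_labels(path) -> Dict[Tuple[str, str], str]:
    """Read a signal/noise label file (node_a, node_b, {signal|noise})."""
    labels: Dict[Tuple[str, str], str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 3 or f[2] not in ("signal", "noise"):
                if lineno == 1:  # header
                    continue
                raise ValueError(f"{path}:{lineno}: expected 'a\\tb\\tsignal|noise'")
            a, b = sorted((f[0], f[1]))
            labels[(a, b)] = f[2]
    return labels


def write_labeled_network(net: LabeledNetwork, edges_path, labels_path, *, config: dict | None = None) -> None:
    """Write a simulated network as an edge-list TSV plus a label TSV."""
    ids = [str(i) for i in range(net.n)]
    write_network(Network(net.weights, ids), edges_path, "edge_list_tsv", config=config)
    lines = ["node_a\tnode_b\tlabel"]
    for (i, j), lab in sorted(net.labels.items()):
        lines.append(f"{ids[i]}\t{ids[j]}\t{lab}")
    _atomic_write(Path(labels_path), "\n".join(lines) + "\n")


def pad_to_square(M, row_ids: Sequence[str], col_ids: Sequence[str]) -> Network:
    """Zero-pad a rectangular (e.g. TF-by-gene) weight matrix to square.

    The output is indexed by the union of row and column ids (row ids
    first, then unseen column ids); entries absent from the rectangular
    input — such as pairs of non-regulator genes — are zero, and an entry
    present in only one direction is mirrored by taking the maximum of
    the two directed values.
    """
    M = np.asarray(M, dtype=float)
    row_ids, col_ids = list(map(str, row_ids)), list(map(str, col_ids))
    if len(set(row_ids)) != len(row_ids) or len(set(col_ids)) != len(col_ids):
        raise ValueError("duplicate ids in row_ids or col_ids")
    if M.shape != (len(row_ids), len(col_ids)):
        raise ValueError(
            f"matrix shape {M.shape} does not match id counts "
            f"({len(row_ids)}, {len(col_ids)})"
        )
    ids = list(row_ids) + [c for c in col_ids if c not in set(row_ids)]
    index = {name: i for i, name in enumerate(ids)}
    n = len(ids)
    D = np.zeros((n, n))
    for r, rn in enumerate(row_ids):
        for c, cn in enumerate(col_ids):
            D[index[rn], index[cn]] = M[r, c]
    W = np.maximum(D, D.T)
    np.fill_diagonal(W, 0.0)
    return Network(W, ids)
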