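"""Input/output and conditioning of directed binary neuronal networks.

A network is a directed, binary adjacency matrix over labelled nodes:
entry ``(i, j) = 1`` means a directed link from node ``i`` to node ``j``
(row = outgoing connections of a neuron).  Self-connections are forbidden;
transfer-entropy pipelines conventionally exclude self-interaction, so a
nonzero diagonal found on disk is zeroed with a logged warning rather than
treated as fatal.

The module also implements the study's data-conditioning conventions:

* a scalar node-ordering index ``(cell_category - 0.5) * layer_category``
  used to sort neurons before matrix assembly, where ``cell_category`` is 0
  for inhibitory and 1 for excitatory neurons and ``layer_category`` in
  1..4 encodes cortical layers 1-3, 4, 5 and 6;
* removal of effectively isolated neurons (no incoming and no outgoing
  link);
* partitioning of a collection of networks into cross-validation folds
  with a seeded choice of validation networks among the training ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    DimensionError,
    EmptyNetworkError,
    ParseError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DirectedBinaryNetwork",
    "DatasetCollection",
    "read_network",
    "write_network",
    "read_annotations",
    "node_order_index",
    "order_nodes",
    "prune_isolated",
    "transpose_network",
    "make_folds",
]


@dataclass
class DirectedBinaryNetwork:
    """A directed binary network over labelled nodes.

    Parameters
    ----------
    adjacency
        ``n x n`` matrix with entries in {0, 1}; ``adjacency[i, j] = 1``
        means a directed link from node ``i`` to node ``j``.
    node_ids
        Ordered node labels, one per row/column.
    annotations
        Optional per-node table with columns ``cell_category`` (0 =
        inhibitory, 1 = excitatory) and ``layer_category`` (1..4), indexed
        like ``node_ids``.
    """

    adjacency: np.ndarray
    node_ids: list[str] = field(default=None)  # type: ignore[assignment]
    annotations: pd.DataFrame | None = None
    name: str = ""

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise DimensionError(f"adjacency must be square, got shape {a.shape}")
        if not np.isin(a, (0, 1)).all():
            raise ParseError("adjacency entries must all be 0 or 1")
        if np.diagonal(a).any():
            raise ParseError("adjacency diagonal must be zero (no self-connections)")
        self.adjacency = a.astype(np.int8)
        if self.node_ids is None:
            self.node_ids = [str(i) for i in range(a.shape[0])]
        if len(self.node_ids) != a.shape[0]:
            raise DimensionError(
                f"{len(self.node_ids)} node ids for a {a.shape[0]}-node matrix"
            )
        if self.annotations is not None and len(self.annotations) != a.shape[0]:
            raise DimensionError("annotation table length does not match node count")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    @property
    def density(self) -> float:
        n = self.n_nodes
        return self.n_edges / (n * (n - 1)) if n > 1 else 0.0

    def out_degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def in_degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0)

    def copy(self) -> "DirectedBinaryNetwork":
        return DirectedBinaryNetwork(
            self.adjacency.copy(),
            list(self.node_ids),
            None if self.annotations is None else self.annotations.copy(),
            self.name,
        )


@dataclass
class DatasetCollection:
    """A set of networks partitioned into cross-validation folds.

    ``fold_of[i]`` is the fold index (0-based) whose *test* split contains
    network ``i``; ``validation_of[f]`` lists the networks used as the
    validation (early-stopping) set when fold ``f`` is the test fold.
    """

    networks: list[DirectedBinaryNetwork]
    fold_of: np.ndarray
    validation_of: dict[int, list[int]]

    @property
    def n_folds(self) -> int:
        return int(self.fold_of.max()) + 1

    def split(self, fold: int) -> tuple[list[int], list[int], list[int]]:
        """Return (train, validation, test) network indices for one fold."""
        test = [i for i in range(len(self.networks)) if self.fold_of[i] == fold]
        val = list(self.validation_of[fold])
        train = [
            i
            for i in range(len(self.networks))
            if self.fold_of[i] != fold and i not in val
        ]
        return train, val, test


def _sniff_delimiter(line: str) -> str | None:
    return "," if "," in line else None  # None -> any whitespace


def read_network(
    path: str | Path,
    fmt: str = "dense",
    n_nodes: int | None = None,
    index_base: int = 0,
    name: str | None = None,
) -> DirectedBinaryNetwork:
    """Read a network from delimited text.

    ``fmt="dense"`` expects a square numeric grid (whitespace- or
    comma-delimited, auto-detected); any nonzero entry is coerced to 1.
    ``fmt="edges"`` expects two columns (source, target); ``n_nodes`` may
    be declared explicitly, otherwise it is inferred from the largest
    index.  ``index_base`` selects 0- or 1-based node indices in edge
    lists.  A nonzero diagonal is zeroed with a warning.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    if fmt == "dense":
        rows = []
        for lineno, ln in enumerate(lines, start=1):
            parts = ln.split(",") if _sniff_delimiter(ln) else ln.split()
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ParseError(f"{path}: ragged rows (lengths {sorted(lengths)})")
        a = np.array(rows)
        if a.shape[0] != a.shape[1]:
            raise DimensionError(f"{path}: dense matrix is {a.shape}, not square")
    elif fmt == "edges":
        edges = []
        for lineno, ln in enumerate(lines, start=1):
            parts = ln.replace(",", " ").split()
            if lineno == 1 and not all(_is_int(p) for p in parts):
                continue  # header row
            if len(parts) < 2 or not all(_is_int(p) for p in parts[:2]):
                raise ParseError(f"{path}: line {lineno}: expected two integer columns")
            edges.append((int(parts[0]) - index_base, int(parts[1]) - index_base))
        if not edges and n_nodes is None:
            raise ParseError(f"{path}: no edges and no declared node count")
        n = n_nodes if n_nodes is not None else max(max(e) for e in edges) + 1
        a = np.zeros((n, n))
        for s, t in edges:
            if not (0 <= s < n and 0 <= t < n):
                raise ParseError(f"{path}: edge ({s},{t}) outside 0..{n - 1}")
            a[s, t] = 1
    else:
        raise ConfigurationError(f"unknown format {fmt!r}")

    a = (a != 0).astype(np.int8)
    if np.diagonal(a).any():
        logger.warning(
            "%s: %d self-loop(s) removed (diagonal forced to zero)",
            path,
            int(np.diagonal(a).sum()),
        )
        np.fill_diagonal(a, 0)
    return DirectedBinaryNetwork(a, name=name or path.stem)


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


def write_network(
    net: DirectedBinaryNetwork,
    path: str | Path,
    fmt: str = "dense",
    delimiter: str = "\t",
) -> None:
    """Write a network as delimited text (dense grid or edge list)."""
    path = Path(path)
    if fmt == "dense":
        np.savetxt(path, net.adjacency, fmt="%d", delimiter=delimiter)
    elif fmt == "edges":
        src, tgt = np.nonzero(net.adjacency)
        np.savetxt(
            path,
            np.column_stack([src, tgt]),
            fmt="%d",
            delimiter=delimiter,
            header="source\ttarget",
            comments="",
        )
    else:
        raise ConfigurationError(f"unknown format {fmt!r}")


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a per-node annotation table.

    Expects columns ``node_id``, ``cell_category`` (0/1) and
    ``layer_category`` (1..4); the delimiter is auto-detected.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"node_id", "cell_category", "layer_category"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: annotation table needs columns {sorted(required)}")
    df = df.set_index("node_id")
    for _, row in df.iterrows():
        node_order_index(int(row["cell_category"]), int(row["layer_category"]))
    return df


def node_order_index(cell_category: int, layer_category: int) -> float:
    """Scalar identity index ``(cell_category - 0.5) * layer_category``.

    Inhibitory neurons (cell 0) map to negative values, excitatory (cell 1)
    to positive, with magnitude increasing with cortical depth category.
    """
    if cell_category not in (0, 1):
        raise ConfigurationError(f"cell_category must be 0 or 1, got {cell_category}")
    if layer_category not in (1, 2, 3, 4):
        raise ConfigurationError(
            f"layer_category must be in 1..4, got {layer_category}"
        )
    return (cell_category - 0.5) * layer_category


def order_nodes(net: DirectedBinaryNetwork) -> DirectedBinaryNetwork:
    """Reorder nodes by ascending order index (stable for ties).

    Requires annotations; rows and columns of the adjacency are permuted
    consistently.
    """
    if net.annotations is None:
        raise ConfigurationError("order_nodes requires per-node annotations")
    idx = np.array(
        [
            node_order_index(int(c), int(l))
            for c, l in zip(
                net.annotations["cell_category"], net.annotations["layer_category"]
            )
        ]
    )
    perm = np.argsort(idx, kind="stable")
    return DirectedBinaryNetwork(
        net.adjacency[np.ix_(perm, perm)],
        [net.node_ids[i] for i in perm],
        net.annotations.iloc[perm],
        net.name,
    )


def prune_isolated(
    net: DirectedBinaryNetwork,
) -> tuple[DirectedBinaryNetwork, list[str]]:
    """Drop nodes with neither incoming nor outgoing links.

    Such neurons are effectively isolated in the slice.  Returns the pruned
    network and the removed node labels (so downstream features and metrics
    can be mapped back to the original labelling).  Idempotent.
    """
    deg = net.out_degrees() + net.in_degrees()
    keep = np.nonzero(deg > 0)[0]
    if keep.size == 0:
        raise EmptyNetworkError("pruning removed every node (network has no links)")
    removed = [net.node_ids[i] for i in np.nonzero(deg == 0)[0]]
    if not removed:
        return net, []
    pruned = DirectedBinaryNetwork(
        net.adjacency[np.ix_(keep, keep)],
        [net.node_ids[i] for i in keep],
        None if net.annotations is None else net.annotations.iloc[keep],
        net.name,
    )
    return pruned, removed


def transpose_network(net: DirectedBinaryNetwork) -> DirectedBinaryNetwork:
    """Swap rows and columns: per-node samples become incoming connections."""
    return DirectedBinaryNetwork(
        net.adjacency.T.copy(),
        list(net.node_ids),
        None if net.annotations is None else net.annotations.copy(),
        f"{net.name}^T" if net.name else "",
    )


def make_folds(
    nets: Sequence[DirectedBinaryNetwork],
    n_folds: int = 5,
    n_validation: int | None = None,
    seed: int = 0,
) -> DatasetCollection:
    """Partition networks into equal test folds with seeded validation picks.

    With 15 networks and 5 folds each test fold holds 3 networks; of the
    remaining 12, ``n_validation`` (default: fold size) are drawn uniformly
    as the validation/early-stopping set and the rest are pure training
    data.  The same seed always yields the same assignment.
    """
    n = len(nets)
    if n % n_folds != 0:
        raise ConfigurationError(
            f"{n} networks cannot be split into {n_folds} equal folds"
        )
    fold_size = n // n_folds
    if n_validation is None:
        n_validation = fold_size
    if n_validation > n - fold_size:
        raise ConfigurationError("validation set larger than the training pool")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    for f in range(n_folds):
        fold_of[perm[f * fold_size : (f + 1) * fold_size]] = f
    validation_of = {}
    for f in range(n_folds):
        pool = np.nonzero(fold_of != f)[0]
        validation_of[f] = sorted(rng.choice(pool, size=n_validation, replace=False))
    return DatasetCollection(list(nets), fold_of, validation_of)
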