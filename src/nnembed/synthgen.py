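"""Synthetic networks emulating the study conditions, and swap perturbations.

Two generators are provided:

* :func:`generate_ba` — Barabási–Albert preferential-attachment control
  networks (the study's 1,000-node controls reach ~40% connection density;
  at 100 nodes an attachment parameter of 26 reproduces that density).
  BA graphs are undirected; by default both directions are set in the
  binary adjacency, with random single-orientation as an option.

* :func:`generate_microconnectome_like` — a stand-in for effective
  (transfer-entropy) networks of cortical microcircuits: directed, binary,
  ~100 nodes, heavy-tailed (near scale-free) degree distributions,
  elevated reciprocity, no self-loops, no isolated nodes.  Connection
  propensities are tied to node *index* (a Zipf profile over positions),
  mirroring the deterministic neuron ordering applied to the real
  datasets, so that independently generated networks share positional hub
  structure the way the study's 15 datasets do.

:func:`swap_edges` implements the degradation perturbation: a chosen
fraction of existing edges is relocated onto previously empty off-diagonal
cells, either within each source row (out-degree sequence exactly
preserved, both density and per-node counts) or anywhere (per-node degrees
broken, total edge count still conserved).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .exceptions import ConfigurationError, InfeasibleSwapError
from .netio import DirectedBinaryNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "SwapSpec",
    "generate_ba",
    "generate_microconnectome_like",
    "swap_edges",
    "swap_series",
    "DEFAULT_SWAP_FRACTIONS",
]

#: The eleven relocation ratios used throughout the degradation analyses.
DEFAULT_SWAP_FRACTIONS = tuple(np.round(np.arange(0, 1.01, 0.1), 1))


@dataclass(frozen=True)
class SwapSpec:
    """How to perturb a network by edge relocation.

    ``fraction`` of the existing edges are moved; with ``preserve_degree``
    the relocation stays within each source row so every node keeps its
    out-degree.
    """

    fraction: float
    preserve_degree: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise ConfigurationError(f"fraction must be in [0,1], got {self.fraction}")


def _round_half_away(x: float) -> int:
    """Round half away from zero (3.5 -> 4), used for edge counts."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def generate_ba(
    n_nodes: int,
    attachment: int,
    seed: int = 0,
    orient: str = "symmetric",
) -> DirectedBinaryNetwork:
    """Barabási–Albert graph as a directed binary network.

    ``orient="symmetric"`` sets both directions for every undirected edge;
    ``orient="random"`` keeps a single, randomly chosen direction.
    """
    if not 1 <= attachment < n_nodes:
        raise ConfigurationError(
            f"attachment must satisfy 1 <= m < n, got m={attachment}, n={n_nodes}"
        )
    g = nx.barabasi_albert_graph(n_nodes, attachment, seed=seed)
    a = np.zeros((n_nodes, n_nodes), dtype=np.int8)
    rng = np.random.default_rng(seed)
    for u, v in g.edges():
        if orient == "symmetric":
            a[u, v] = a[v, u] = 1
        elif orient == "random":
            if rng.random() < 0.5:
                a[u, v] = 1
            else:
                a[v, u] = 1
        else:
            raise ConfigurationError(f"unknown orientation {orient!r}")
    return DirectedBinaryNetwork(a, name=f"ba_n{n_nodes}_m{attachment}_s{seed}")


def _zipf_weights(n: int, exponent: float) -> np.ndarray:
    # Expected-degree profile of a finite scale-free network with
    # P(k) ~ k^-exponent: rank-based weights w_r ~ r^(-1/(exponent-1)).
    alpha = 1.0 / (exponent - 1.0)
    return np.arange(1, n + 1, dtype=float) ** (-alpha)


def generate_microconnectome_like(
    n_nodes: int = 100,
    density: float = 0.1,
    heavy_tail_exponent: float = 2.2,
    reciprocity: float = 0.3,
    seed: int = 0,
) -> DirectedBinaryNetwork:
    """Directed binary network with heavy-tailed degrees and set reciprocity.

    A directed Chung–Lu-style construction: node ``i`` carries a Zipf
    propensity ``w_i = (i+1)^(-1/(gamma-1))`` used for both its out- and
    in-connections, and edge ``(i, j)`` is present with probability
    ``min(1, c * w_i * w_j)`` where ``c`` is calibrated by bisection so the
    expected density matches ``density``.  Reciprocity (fraction of edges
    whose reverse also exists) is then adjusted toward the target by
    converting unreciprocated edges into mutual pairs while deleting other
    single edges, conserving the edge count.  Finally any isolated node is
    reattached with one random edge, so a single pruning pass is a no-op.
    """
    if not 0 < density < 1:
        raise ConfigurationError(f"density must be in (0,1), got {density}")
    if heavy_tail_exponent <= 1:
        raise ConfigurationError("heavy_tail_exponent must exceed 1")
    n = n_nodes
    target_edges = density * n * (n - 1)
    w = _zipf_weights(n, heavy_tail_exponent)
    ww = np.outer(w, w)
    np.fill_diagonal(ww, 0.0)

    def expected_edges(c: float) -> float:
        return float(np.minimum(1.0, c * ww).sum())

    lo, hi = 0.0, 1.0
    while expected_edges(hi) < target_edges:
        hi *= 2.0
        if hi > 1e12:
            raise ConfigurationError("density too high for this size/exponent")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if expected_edges(mid) < target_edges:
            lo = mid
        else:
            hi = mid
    p = np.minimum(1.0, hi * ww)

    rng = np.random.default_rng(seed)
    a = (rng.random((n, n)) < p).astype(np.int8)
    np.fill_diagonal(a, 0)

    _adjust_reciprocity(a, reciprocity, rng)

    # reattach isolated nodes so one pruning pass leaves the network intact
    deg = a.sum(axis=0) + a.sum(axis=1)
    for i in np.nonzero(deg == 0)[0]:
        j = int(rng.integers(n - 1))
        j += j >= i
        if rng.random() < 0.5:
            a[i, j] = 1
        else:
            a[j, i] = 1

    return DirectedBinaryNetwork(a, name=f"micro_n{n}_s{seed}")


def _adjust_reciprocity(a: np.ndarray, target: float, rng: np.random.Generator):
    """Convert single edges to mutual pairs (edge count conserved) in place."""
    single = np.argwhere((a == 1) & (a.T == 0))
    n_edges = int(a.sum())
    if n_edges == 0:
        return
    mutual = n_edges - len(single)
    deficit_pairs = int((target * n_edges - mutual) // 2)
    if deficit_pairs <= 0:
        # too reciprocal: break mutual pairs, relocating one direction of
        # each onto a random empty off-diagonal cell (edge count conserved)
        excess_pairs = int((mutual - target * n_edges) // 2)
        if excess_pairs <= 0:
            return
        n = a.shape[0]
        pairs = np.argwhere((a == 1) & (a.T == 1))
        pairs = pairs[pairs[:, 0] < pairs[:, 1]]
        take = rng.permutation(len(pairs))[:excess_pairs]
        for i, j in pairs[take]:
            empty = np.argwhere((a == 0) & (a.T == 0))
            empty = empty[empty[:, 0] != empty[:, 1]]
            if len(empty) == 0:
                break
            u, v = empty[rng.integers(len(empty))]
            a[j, i] = 0
            a[u, v] = 1
        return
    order = rng.permutation(len(single))
    promoted = 0
    removed: set[tuple[int, int]] = set()
    k = 0
    for idx in order:
        if promoted >= deficit_pairs or k >= len(order) - 1:
            break
        i, j = single[idx]
        if (i, j) in removed or a[j, i] == 1:
            continue
        # find a sacrificial single edge distinct from (i, j)
        while k < len(order):
            u, v = single[order[k]]
            k += 1
            if (u, v) not in removed and (u, v) != (i, j) and a[v, u] == 0:
                a[u, v] = 0
                removed.add((u, v))
                a[j, i] = 1
                promoted += 1
                break


def swap_edges(net: DirectedBinaryNetwork, spec: SwapSpec) -> DirectedBinaryNetwork:
    """Relocate a fraction of edges onto previously empty cells.

    Exactly ``round(fraction * n_edges)`` edges (round half away from
    zero) are removed and placed on off-diagonal cells that are empty
    after the removal (so a full swap of a dense row remains feasible),
    never on the diagonal.  Total edge count is conserved in both modes;
    with ``preserve_degree`` relocation stays within each source row, so
    the out-degree sequence is exactly invariant.
    """
    a0 = net.adjacency
    edges = np.argwhere(a0 == 1)
    if len(edges) == 0:
        raise InfeasibleSwapError("network has no edges to swap")
    k = _round_half_away(spec.fraction * len(edges))
    if k == 0:
        return net.copy()
    rng = np.random.default_rng(spec.seed)
    chosen = edges[rng.choice(len(edges), size=k, replace=False)]
    a = a0.copy()
    n = a.shape[0]
    if spec.preserve_degree:
        rows = np.unique(chosen[:, 0])
        for i in rows:
            cols = chosen[chosen[:, 0] == i, 1]
            a[i, cols] = 0
            free = np.nonzero(a[i] == 0)[0]
            free = free[free != i]
            if len(free) < len(cols):
                raise InfeasibleSwapError(
                    f"row {i}: {len(cols)} edges to move but only {len(free)} empty cells"
                )
            a[i, rng.choice(free, size=len(cols), replace=False)] = 1
    else:
        a[chosen[:, 0], chosen[:, 1]] = 0
        empty = np.nonzero(a.ravel() == 0)[0]
        empty = empty[empty % n != empty // n]  # drop diagonal
        if len(empty) < k:
            raise InfeasibleSwapError(
                f"{k} edges to move but only {len(empty)} empty off-diagonal cells"
            )
        a.ravel()[rng.choice(empty, size=k, replace=False)] = 1
    return DirectedBinaryNetwork(
        a, list(net.node_ids),
        None if net.annotations is None else net.annotations.copy(),
        f"{net.name}_swap{spec.fraction:g}",
    )


def swap_series(
    net: DirectedBinaryNetwork,
    fractions=DEFAULT_SWAP_FRACTIONS,
    preserve_degree: bool = True,
    n_reps: int = 5,
    seed: int = 0,
) -> list[tuple[float, list[DirectedBinaryNetwork]]]:
    """Seeded replicates of :func:`swap_edges` across a fraction ladder.

    Fraction 0 returns the original network once; each nonzero fraction
    gets ``n_reps`` independently seeded replicates.
    """
    fr = list(fractions)
    if fr != sorted(fr):
        raise ConfigurationError("fractions must be sorted ascending")
    ss = np.random.SeedSequence(seed)
    out = []
    for f in fr:
        if f == 0:
            out.append((f, [net]))
            continue
        reps = []
        for _ in range(n_reps):
            child_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            reps.append(swap_edges(net, SwapSpec(f, preserve_degree, child_seed)))
        out.append((f, reps))
    return out
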