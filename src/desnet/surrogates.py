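"""Topology-destroying controls.

Two surrogate families isolate the contribution of native wiring:

* type-aware, degree-preserving rewiring — Maslov-Sneppen double-edge
  swaps ``(u -> v, x -> y) => (u -> y, x -> v)`` accepted only when the new
  edges are absent, create no self-loop, and ``class(v) == class(y)``, so
  every node keeps its in- and out-degree and every edge keeps its endpoint
  class pair.  Weights travel with the swapped target assignment.
* pathway lesioning — uniform removal of a stated fraction of the edges in
  a named (source class -> destination class) pathway, e.g. dropping 50% of
  KC -> MBON edges, leaving all other edges untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError, require
from .graph import ConnectomeGraph

__all__ = ["SurrogateSpec", "rewire_type_preserving", "lesion_edges"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SurrogateSpec:
    """Parameters for surrogate construction.

    ``n_swap_multiplier`` counts swap *attempts* per edge (default 10x the
    edge count), not acceptances.  The lesion class pair defaults to the
    KC -> MBON readout pathway with half the edges dropped.
    """

    kind: str = "rewired_type"  # "rewired_type" | "lesion"
    n_swap_multiplier: int = 10
    lesion_src_class: str = "KC"
    lesion_dst_class: str = "MBON"
    lesion_drop: float = 0.5
    seed: int = 0

    def __post_init__(self):
        require(self.kind in ("rewired_type", "lesion"), f"unknown surrogate kind {self.kind!r}")
        require(0 <= self.lesion_drop <= 1, "lesion_drop must lie in [0, 1]")
        require(self.n_swap_multiplier >= 1, "n_swap_multiplier must be >= 1")


def _directed_edges(graph: ConnectomeGraph) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    w = graph.weights.copy()
    np.fill_diagonal(w, 0.0)
    src, dst = np.nonzero(w)
    return src, dst, w[src, dst]


def rewire_type_preserving(graph: ConnectomeGraph, spec: SurrogateSpec) -> ConnectomeGraph:
    """Degree-preserving, class-pair-preserving randomization of the edge set.

    Performs ``n_swap_multiplier * n_edges`` attempted double-edge swaps.
    Graphs with no swappable pair are returned as an identical copy (logged).
    For undirected graphs each edge is handled once in canonical order and
    symmetry of the weight matrix is restored afterwards.
    """
    rng = np.random.default_rng(spec.seed)
    classes = graph.node_classes

    src, dst, wts = _directed_edges(graph)
    if not graph.directed:
        keep = src < dst
        src, dst, wts = src[keep], dst[keep], wts[keep]
    n_edges = len(src)
    require(n_edges >= 2, "graph needs at least 2 edges to rewire")

    src = src.copy()
    dst = dst.copy()
    present: set[tuple[int, int]] = set()
    for u, v in zip(src, dst):
        present.add((int(u), int(v)))
        if not graph.directed:
            present.add((int(v), int(u)))

    def has_edge(u: int, v: int) -> bool:
        return (u, v) in present

    def drop_edge(u: int, v: int) -> None:
        present.discard((u, v))
        if not graph.directed:
            present.discard((v, u))

    def add_edge(u: int, v: int) -> None:
        present.add((u, v))
        if not graph.directed:
            present.add((v, u))

    attempts = spec.n_swap_multiplier * n_edges
    accepted = 0
    pairs = rng.integers(0, n_edges, size=(attempts, 2))
    for i, j in pairs:
        if i == j:
            continue
        u, v = int(src[i]), int(dst[i])
        x, y = int(src[j]), int(dst[j])
        if classes[v] != classes[y]:
            continue
        if u == y or x == v:
            continue  # would create a self-loop
        if (u, y) in present or (x, v) in present:
            continue
        drop_edge(u, v)
        drop_edge(x, y)
        add_edge(u, y)
        add_edge(x, v)
        dst[i], dst[j] = y, v
        accepted += 1

    if accepted == 0:
        logger.info("rewire_type_preserving: no swap accepted; returning an identical copy")

    n = graph.n_nodes
    w_new = np.zeros((n, n))
    for u, v, w in zip(src, dst, wts):
        w_new[u, v] += w
        if not graph.directed:
            w_new[v, u] += w
    return ConnectomeGraph(
        node_ids=graph.node_ids,
        node_classes=graph.node_classes,
        weights=w_new,
        directed=graph.directed,
    )


def lesion_edges(graph: ConnectomeGraph, spec: SurrogateSpec) -> ConnectomeGraph:
    """Remove a uniform random fraction of the edges in one class pathway.

    Exactly ``round_half_even(lesion_drop * m)`` of the ``m`` edges whose
    (source class, destination class) matches the spec are removed; every
    other edge is untouched.  Raises if the pathway has no edges.
    """
    rng = np.random.default_rng(spec.seed)
    classes = graph.node_classes

    src, dst, _ = _directed_edges(graph)
    if not graph.directed:
        keep = src < dst
        src, dst = src[keep], dst[keep]
    if graph.directed:
        match = np.array(
            [classes[u] == spec.lesion_src_class and classes[v] == spec.lesion_dst_class
             for u, v in zip(src, dst)]
        )
    else:
        match = np.array(
            [{classes[u], classes[v]} == {spec.lesion_src_class, spec.lesion_dst_class}
             for u, v in zip(src, dst)]
        )
    m = int(match.sum())
    if m == 0:
        raise ValidationError(
            f"no edges match class pair {spec.lesion_src_class} -> {spec.lesion_dst_class}"
        )
    # round half to even for cross-platform determinism
    n_drop = int(np.round(spec.lesion_drop * m))
    matching_idx = np.nonzero(match)[0]
    dropped = rng.choice(matching_idx, size=n_drop, replace=False) if n_drop else np.array([], dtype=int)

    w_new = graph.weights.copy()
    np.fill_diagonal(w_new, 0.0)
    for k in dropped:
        u, v = int(src[k]), int(dst[k])
        w_new[u, v] = 0.0
        if not graph.directed:
            w_new[v, u] = 0.0
    return ConnectomeGraph(
        node_ids=graph.node_ids,
        node_classes=graph.node_classes,
        weights=w_new,
        directed=graph.directed,
    )
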