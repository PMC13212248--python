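"""Graph representation and Hamiltonian construction.

A benchmark graph is a node-labelled, class-labelled weighted adjacency
matrix together with a role assignment (source nodes, target sinks,
distractor sinks).  The coherent generator of the transport model is built
from the symmetrized weighted Laplacian,

    H0 = -gamma * L_sym,      L_sym = D_sym - W_sym,

where ``W_sym`` is either ``(W + W.T) / 2`` directly or, for directed
benchmarks, the symmetrization of the row-normalized transition matrix
``p(u -> v) = w_uv / sum_v w_uv``.  Diagonal disorder enters as node-energy
heterogeneity ``H = H0 + diag(E)`` with ``E_i ~ Uniform[-eps, +eps]``,
a phenomenological stand-in for excitability/threshold heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError, require

__all__ = [
    "ConnectomeGraph",
    "RoleAssignment",
    "HamiltonianSpec",
    "DisorderSpec",
    "symmetrize_coupling",
    "build_laplacian",
    "draw_disorder",
    "build_hamiltonian",
]


@dataclass(frozen=True)
class ConnectomeGraph:
    """Weighted, class-labelled graph over named nodes.

    Parameters
    ----------
    node_ids
        Unique string labels; their order fixes the index order of every
        matrix derived from the graph.
    node_classes
        Per-node categorical label (e.g. ``PN`` / ``KC`` / ``MBON``).
    weights
        ``N x N`` nonnegative matrix, entry ``(u, v)`` the weight of the
        directed edge ``u -> v``.  The diagonal is ignored by Laplacian
        construction.
    directed
        Whether the weight matrix should be read as directed.
    """

    node_ids: tuple[str, ...]
    node_classes: tuple[str, ...]
    weights: np.ndarray
    directed: bool = True

    def __post_init__(self):
        object.__setattr__(self, "node_ids", tuple(str(n) for n in self.node_ids))
        object.__setattr__(self, "node_classes", tuple(str(c) for c in self.node_classes))
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        n = len(self.node_ids)
        require(n >= 2, f"graph needs at least 2 nodes, got {n}")
        require(len(set(self.node_ids)) == n, "node ids must be unique")
        require(len(self.node_classes) == n, "node_classes length must match node_ids")
        require(w.shape == (n, n), f"weight matrix shape {w.shape} != ({n}, {n})")
        require(np.all(np.isfinite(w)), "weights must be finite")
        require(bool(np.all(w >= 0)), "weights must be nonnegative")
        if not self.directed:
            require(np.allclose(w, w.T), "undirected graph requires a symmetric weight matrix")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def index_of(self, node_id: str) -> int:
        try:
            return self.node_ids.index(node_id)
        except ValueError:
            raise ValidationError(f"unknown node id {node_id!r}") from None

    def indices_of(self, node_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.index_of(n) for n in node_ids], dtype=int)

    def class_of(self, node_id: str) -> str:
        return self.node_classes[self.index_of(node_id)]

    def edge_list(self) -> list[tuple[str, str, float]]:
        """Directed edge list ``(src, dst, weight)``; for undirected graphs
        each edge is reported once with ``src`` index < ``dst`` index."""
        rows, cols = np.nonzero(self.weights)
        out = []
        for i, j in zip(rows, cols):
            if i == j:
                continue
            if not self.directed and i > j:
                continue
            out.append((self.node_ids[i], self.node_ids[j], float(self.weights[i, j])))
        return out

    def fingerprint(self) -> str:
        """Stable content hash of node ids, classes and weights."""
        import hashlib

        h = hashlib.sha256()
        h.update("|".join(self.node_ids).encode())
        h.update("|".join(self.node_classes).encode())
        h.update(np.ascontiguousarray(self.weights).tobytes())
        h.update(b"directed" if self.directed else b"undirected")
        return h.hexdigest()[:16]


@dataclass(frozen=True)
class RoleAssignment:
    """Source nodes and target/distractor sink attachment nodes."""

    source_nodes: tuple[str, ...]
    target_sinks: tuple[str, ...]
    distractor_sinks: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "source_nodes", tuple(self.source_nodes))
        object.__setattr__(self, "target_sinks", tuple(self.target_sinks))
        object.__setattr__(self, "distractor_sinks", tuple(self.distractor_sinks))
        require(len(self.source_nodes) > 0, "source set must be nonempty")
        overlap = set(self.target_sinks) & set(self.distractor_sinks)
        require(not overlap, f"target and distractor sinks overlap: {sorted(overlap)}")
        require(
            len(self.target_sinks) + len(self.distractor_sinks) > 0,
            "sink set (targets plus distractors) must be nonempty",
        )

    @property
    def all_sinks(self) -> tuple[str, ...]:
        return self.target_sinks + self.distractor_sinks

    def validate_against(self, graph: ConnectomeGraph) -> None:
        known = set(graph.node_ids)
        for label, nodes in (
            ("source", self.source_nodes),
            ("target sink", self.target_sinks),
            ("distractor sink", self.distractor_sinks),
        ):
            missing = [n for n in nodes if n not in known]
            require(not missing, f"{label} nodes not in graph: {missing}")


@dataclass(frozen=True)
class HamiltonianSpec:
    """Coupling strength and normalization convention for H0 = -gamma L_sym."""

    gamma: float = 1.0
    row_normalize: bool = False

    def __post_init__(self):
        require(self.gamma > 0, "gamma must be positive")


@dataclass(frozen=True)
class DisorderSpec:
    """Amplitude and seed for uniform diagonal disorder E_i ~ U[-eps, +eps]."""

    epsilon: float = 0.0
    seed: int = 0

    def __post_init__(self):
        require(self.epsilon >= 0, "epsilon must be nonnegative")


def symmetrize_coupling(graph: ConnectomeGraph, spec: HamiltonianSpec) -> np.ndarray:
    """Symmetric nonnegative coupling matrix entering the Laplacian.

    With ``spec.row_normalize`` the directed weights are first converted to
    transition probabilities per row (rows with zero out-weight stay zero)
    and then symmetrized; otherwise ``(W + W.T)/2`` is returned directly.
    The diagonal is zeroed in both cases.
    """
    if spec.row_normalize:
        require(graph.directed, "row_normalize requires a directed graph")
        w = graph.weights.copy()
        np.fill_diagonal(w, 0.0)
        out = w.sum(axis=1)
        p = np.divide(w, out[:, None], out=np.zeros_like(w), where=out[:, None] > 0)
        w_sym = (p + p.T) / 2.0
    else:
        w_sym = (graph.weights + graph.weights.T) / 2.0
    np.fill_diagonal(w_sym, 0.0)
    return w_sym


def build_laplacian(w_sym: np.ndarray) -> np.ndarray:
    """Symmetric graph Laplacian ``L = diag(row sums) - W``; PSD, zero row sums."""
    w_sym = np.asarray(w_sym, dtype=float)
    require(w_sym.ndim == 2 and w_sym.shape[0] == w_sym.shape[1], "coupling matrix must be square")
    require(np.allclose(w_sym, w_sym.T, atol=1e-12), "coupling matrix must be symmetric")
    require(bool(np.all(w_sym >= 0)), "coupling matrix must be nonnegative")
    w = w_sym.copy()
    np.fill_diagonal(w, 0.0)
    return np.diag(w.sum(axis=1)) - w


def draw_disorder(n: int, spec: DisorderSpec) -> np.ndarray:
    """Node-energy vector of ``n`` iid Uniform[-eps, +eps] draws; seed-reproducible."""
    require(n >= 1, "need at least one node")
    if spec.epsilon == 0:
        return np.zeros(n)
    rng = np.random.default_rng(spec.seed)
    return rng.uniform(-spec.epsilon, spec.epsilon, size=n)


def build_hamiltonian(l_sym: np.ndarray, spec: HamiltonianSpec, energies: np.ndarray) -> np.ndarray:
    """Real symmetric Hamiltonian ``H = -gamma * L_sym + diag(E)``."""
    l_sym = np.asarray(l_sym, dtype=float)
    energies = np.asarray(energies, dtype=float)
    require(
        l_sym.ndim == 2 and l_sym.shape[0] == l_sym.shape[1] and energies.shape == (l_sym.shape[0],),
        f"dimension mismatch: L is {l_sym.shape}, E is {energies.shape}",
    )
    require(np.allclose(l_sym, l_sym.T, atol=1e-12), "Laplacian must be symmetric")
    return -spec.gamma * l_sym + np.diag(energies)


def hamiltonian_for(
    graph: ConnectomeGraph,
    ham_spec: HamiltonianSpec,
    disorder: DisorderSpec | None = None,
) -> np.ndarray:
    """Convenience: coupling -> Laplacian -> Hamiltonian with a disorder draw."""
    w_sym = symmetrize_coupling(graph, ham_spec)
    l_sym = build_laplacian(w_sym)
    if disorder is None:
        energies = np.zeros(graph.n_nodes)
    else:
        energies = draw_disorder(graph.n_nodes, disorder)
    return build_hamiltonian(l_sym, ham_spec, energies)
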