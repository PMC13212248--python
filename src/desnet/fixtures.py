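"""Synthetic benchmark substrates.

Three generator families emulate the structural classes of the archived
benchmark graphs so the whole pipeline builds and tests without any
download:

* analytic toys (two-site, chain, star) with closed-form spectra and
  dynamics for engine verification;
* a mushroom-body-like motif: sparse expansion (PN -> KC) followed by
  convergent readout (KC -> MBON), with PN sources and a target/distractor
  split of the MBON layer;
* a stochastic-block-model proxy for larger, modular substrates.

All generators are pure functions of their spec, seed included.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import require
from .graph import ConnectomeGraph, RoleAssignment

__all__ = ["MotifSpec", "make_toy_graph", "make_mb_motif", "make_sbm_proxy"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MotifSpec:
    """Layer sizes and wiring densities of the expansion/readout motif.

    Defaults give a compact motif of the benchmark's structural class:
    10 projection-neuron (PN) sources, a 4:1 Kenyon-cell (KC) expansion
    layer in which each KC samples roughly 3 of the 10 PNs
    (``pn_kc_sparsity = 0.3``), and 10 mushroom-body output neurons (MBON)
    each receiving a convergent draw of 20 KC inputs, split 5 targets /
    5 distractors.
    """

    n_pn: int = 10
    n_kc: int = 40
    n_mbon: int = 10
    pn_kc_sparsity: float = 0.3
    kc_mbon_convergence: int = 20
    n_targets: int = 5
    n_distractors: int = 5
    weight_mode: str = "unit"  # "unit" | "lognormal"
    weight_sigma: float = 0.5  # log-normal sigma when weight_mode == "lognormal"
    seed: int = 0

    def __post_init__(self):
        require(self.n_pn >= 1 and self.n_kc >= 1 and self.n_mbon >= 1, "layer sizes must be positive")
        require(0 < self.pn_kc_sparsity <= 1, "pn_kc_sparsity must lie in (0, 1]")
        require(1 <= self.kc_mbon_convergence <= self.n_kc, "convergence must lie in [1, n_kc]")
        require(
            self.n_targets + self.n_distractors <= self.n_mbon,
            "target + distractor count must not exceed the MBON layer",
        )
        require(self.n_targets + self.n_distractors >= 1, "need at least one sink")
        require(self.weight_mode in ("unit", "lognormal"), f"unknown weight mode {self.weight_mode!r}")


def make_toy_graph(
    kind: str,
    size: int = 2,
    detuning: float = 0.0,
    coupling: float = 1.0,
) -> tuple[ConnectomeGraph, RoleAssignment, np.ndarray]:
    """Analytic test substrates; returns (graph, roles, site energies).

    ``two_site`` carries an explicit coupling J and site-energy detuning
    Delta for closed-form checks; ``chain`` and ``star`` carry unit weights
    with the source at one end / the center and the target sink at the
    other end / a leaf.
    """
    require(size >= 2, "toy graphs need at least 2 nodes")
    if kind == "two_site":
        ids = ("a", "b")
        w = np.array([[0.0, coupling], [coupling, 0.0]])
        graph = ConnectomeGraph(ids, ("site", "site"), w, directed=False)
        roles = RoleAssignment(source_nodes=("a",), target_sinks=("b",))
        energies = np.array([0.0, detuning])
        return graph, roles, energies
    if kind == "chain":
        ids = tuple(f"n{i}" for i in range(size))
        w = np.zeros((size, size))
        for i in range(size - 1):
            w[i, i + 1] = w[i + 1, i] = 1.0
        graph = ConnectomeGraph(ids, ("site",) * size, w, directed=False)
        roles = RoleAssignment(source_nodes=(ids[0],), target_sinks=(ids[-1],))
        return graph, roles, np.zeros(size)
    if kind == "star":
        ids = ("hub",) + tuple(f"leaf{i}" for i in range(size - 1))
        w = np.zeros((size, size))
        w[0, 1:] = w[1:, 0] = 1.0
        graph = ConnectomeGraph(ids, ("site",) * size, w, directed=False)
        roles = RoleAssignment(source_nodes=("hub",), target_sinks=(ids[1],))
        return graph, roles, np.zeros(size)
    raise ValueError(f"unknown toy graph kind {kind!r}")


def make_mb_motif(spec: MotifSpec = MotifSpec()) -> tuple[ConnectomeGraph, RoleAssignment]:
    """Directed sparse-expansion / convergent-readout motif.

    PN -> KC edges are independent Bernoulli draws at ``pn_kc_sparsity``;
    each MBON receives ``kc_mbon_convergence`` uniformly chosen (distinct)
    KC inputs.  Roles: every PN is a source; the first ``n_targets`` MBONs
    are target sinks, the next ``n_distractors`` are distractor sinks.
    Unreachable sinks are reported with a logged warning, not an error.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pn + spec.n_kc + spec.n_mbon
    ids = (
        [f"PN{i}" for i in range(spec.n_pn)]
        + [f"KC{i}" for i in range(spec.n_kc)]
        + [f"MBON{i}" for i in range(spec.n_mbon)]
    )
    classes = ["PN"] * spec.n_pn + ["KC"] * spec.n_kc + ["MBON"] * spec.n_mbon
    w = np.zeros((n, n))

    def _weight(size: int) -> np.ndarray:
        if spec.weight_mode == "lognormal":
            return rng.lognormal(mean=0.0, sigma=spec.weight_sigma, size=size)
        return np.ones(size)

    pn_block = rng.random((spec.n_pn, spec.n_kc)) < spec.pn_kc_sparsity
    # a KC with no PN input is disconnected from the sources; give it one claw
    for j in np.nonzero(~pn_block.any(axis=0))[0]:
        pn_block[rng.integers(spec.n_pn), j] = True
    src_pn, dst_kc = np.nonzero(pn_block)
    w[src_pn, spec.n_pn + dst_kc] = _weight(len(src_pn))

    for m in range(spec.n_mbon):
        kc_in = rng.choice(spec.n_kc, size=spec.kc_mbon_convergence, replace=False)
        w[spec.n_pn + kc_in, spec.n_pn + spec.n_kc + m] = _weight(spec.kc_mbon_convergence)

    graph = ConnectomeGraph(tuple(ids), tuple(classes), w, directed=True)
    mbon_ids = ids[spec.n_pn + spec.n_kc :]
    roles = RoleAssignment(
        source_nodes=tuple(ids[: spec.n_pn]),
        target_sinks=tuple(mbon_ids[: spec.n_targets]),
        distractor_sinks=tuple(mbon_ids[spec.n_targets : spec.n_targets + spec.n_distractors]),
    )

    g = nx.from_numpy_array(w, create_using=nx.DiGraph)
    reachable: set[int] = set()
    for s in range(spec.n_pn):
        reachable |= nx.descendants(g, s) | {s}
    sink_idx = graph.indices_of(roles.all_sinks)
    unreachable = [graph.node_ids[i] for i in sink_idx if i not in reachable]
    if unreachable:
        logger.warning("make_mb_motif: %d sink(s) unreachable from sources: %s",
                       len(unreachable), unreachable)
    return graph, roles


def make_sbm_proxy(
    n_nodes: int,
    block_sizes: list[int],
    p_in: float,
    p_out: float,
    seed: int = 0,
) -> tuple[ConnectomeGraph, RoleAssignment]:
    """Undirected stochastic-block-model proxy substrate.

    Within-block edges appear with probability ``p_in``, between-block
    edges with ``p_out``.  The first block's nodes are sources; the second
    block is split half/half into target and distractor sinks.
    """
    require(sum(block_sizes) == n_nodes, "block sizes must sum to n_nodes")
    require(len(block_sizes) >= 2, "need at least 2 blocks")
    require(0 <= p_out <= p_in <= 1, "need 0 <= p_out <= p_in <= 1")

    k = len(block_sizes)
    p = np.full((k, k), p_out)
    np.fill_diagonal(p, p_in)
    g = nx.stochastic_block_model(block_sizes, p.tolist(), seed=int(seed))
    w = nx.to_numpy_array(g, dtype=float)

    ids = []
    classes = []
    for b, size in enumerate(block_sizes):
        ids += [f"B{b}_{i}" for i in range(size)]
        classes += [f"block{b}"] * size
    graph = ConnectomeGraph(tuple(ids), tuple(classes), w, directed=False)

    b0 = block_sizes[0]
    b1 = block_sizes[1]
    second = ids[b0 : b0 + b1]
    half = max(b1 // 2, 1)
    roles = RoleAssignment(
        source_nodes=tuple(ids[:b0]),
        target_sinks=tuple(second[:half]),
        distractor_sinks=tuple(second[half : min(2 * half, b1)]),
    )
    return graph, roles
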