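import numpy as np
import pytest

from desnet import (
    ConnectomeGraph,
    HamiltonianSpec,
    MotifSpec,
    RoleAssignment,
    make_mb_motif,
    make_toy_graph,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def two_site():
    graph, roles, energies = make_toy_graph("two_site", coupling=1.0)
    return graph, roles, energies


@pytest.fixture
def small_mb():
    """Compact expansion/readout motif used by sweep and surrogate tests."""
    spec = MotifSpec(
        n_pn=4, n_kc=12, n_mbon=6, pn_kc_sparsity=0.4, kc_mbon_convergence=6,
        n_targets=2, n_distractors=2, seed=7,
    )
    graph, roles = make_mb_motif(spec)
    return graph, roles


@pytest.fixture
def directed_6node(rng):
    """Random 6-node directed weighted graph for normalization oracles."""
    w = rng.uniform(0.0, 2.0, size=(6, 6)) * (rng.random((6, 6)) < 0.6)
    np.fill_diagonal(w, 0.0)
    ids = tuple("abcdef")
    return ConnectomeGraph(ids, ("c",) * 6, w, directed=True)


def random_instance(rng, n_max=12):
    """Random small graph + roles + parameters for conservation/positivity sweeps."""
    n = int(rng.integers(3, n_max + 1))
    w = rng.uniform(0, 1, (n, n)) * (rng.random((n, n)) < 0.5)
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    # guarantee connectivity of a spanning path so dynamics are nontrivial
    for i in range(n - 1):
        if w[i, i + 1] == 0:
            w[i, i + 1] = w[i + 1, i] = rng.uniform(0.2, 1.0)
    ids = tuple(f"n{i}" for i in range(n))
    graph = ConnectomeGraph(ids, ("c",) * n, w, directed=False)
    n_sinks = int(rng.integers(1, 3))
    sink_nodes = list(rng.choice(n, size=n_sinks + 1, replace=False))
    roles = RoleAssignment(
        source_nodes=(ids[sink_nodes[-1]],),
        target_sinks=(ids[sink_nodes[0]],),
        distractor_sinks=tuple(ids[k] for k in sink_nodes[1:-1]),
    )
    kappa = float(rng.uniform(0, 10))
    epsilon = float(rng.uniform(0, 5))
    return graph, roles, kappa, epsilon
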