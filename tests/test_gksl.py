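import numpy as np
import pytest

from desnet import (
    RunParams,
    ValidationError,
    absorption_readout,
    build_liouvillian,
    initial_state,
    propagate_gksl,
)
from desnet.gksl import apply_generator
from desnet.graph import HamiltonianSpec, build_laplacian, symmetrize_coupling, build_hamiltonian
from desnet.sweep import simulate_run

from conftest import random_instance


def dense_generator_action(h, attach, etas, kappa, rho):
    """Independent term-by-term evaluation of the master equation on one state.

    Works directly with matrix products of the written-out equation rather
    than the Kronecker-lifted superoperator."""
    n = h.shape[0]
    m = rho.shape[0]
    h_aug = np.zeros((m, m), dtype=complex)
    h_aug[:n, :n] = h
    drho = -1j * (h_aug @ rho - rho @ h_aug)
    for k in range(n):
        pi = np.zeros((m, m))
        pi[k, k] = 1.0
        drho += kappa * (pi @ rho @ pi - 0.5 * (pi @ rho + rho @ pi))
    for s, (a, eta) in enumerate(zip(attach, etas)):
        j = np.zeros((m, m))
        j[n + s, a] = 1.0
        drho += eta * (j @ rho @ j.conj().T - 0.5 * (j.conj().T @ j @ rho + rho @ j.conj().T @ j))
    return drho


class TestInitialState:
    def test_single_source_forced(self):
        s = initial_state(3, [0], 1)
        np.testing.assert_array_equal(np.real(np.diag(s.rho)[:3]), [1.0, 0.0, 0.0])

    def test_many_sources_equal_mass(self):
        s = initial_state(12, range(10), 0)
        np.testing.assert_allclose(np.real(np.diag(s.rho)[:10]), 0.1)

    def test_trace_one_and_diagonal(self):
        s = initial_state(5, [1, 3], 2)
        assert abs(np.trace(s.rho) - 1) < 1e-14
        assert np.abs(s.rho - np.diag(np.diag(s.rho))).max() == 0.0

    def test_coherent_option_is_pure(self):
        s = initial_state(4, [0, 2], 1, coherent=True)
        evals = np.linalg.eigvalsh(s.rho)
        assert abs(evals[-1] - 1.0) < 1e-12

    def test_empty_sources_rejected(self):
        with pytest.raises(ValidationError):
            initial_state(3, [], 1)


class TestLiouvillian:
    def test_kappa_zero_no_sinks_is_pure_commutator(self, rng):
        h = rng.normal(size=(4, 4))
        h = (h + h.T) / 2
        liouv = build_liouvillian(h, [], [], RunParams(kappa=0.0))
        rho = rng.normal(size=(4, 4)) + 1j * rng.normal(size=(4, 4))
        rho = (rho + rho.conj().T) / 2
        np.testing.assert_allclose(apply_generator(liouv, rho),
                                   -1j * (h @ rho - rho @ h), atol=1e-12)

    def test_pure_dephasing_conserves_diagonal(self, rng):
        liouv = build_liouvillian(np.zeros((3, 3)), [], [], RunParams(kappa=2.5))
        rho = rng.normal(size=(3, 3)) + 1j * rng.normal(size=(3, 3))
        rho = (rho + rho.conj().T) / 2
        np.testing.assert_allclose(np.diag(apply_generator(liouv, rho)), 0.0, atol=1e-14)

    def test_matches_dense_term_by_term_oracle(self, rng):
        h = rng.normal(size=(4, 4))
        h = (h + h.T) / 2
        attach, etas, kappa = [1, 3], [1.0, 0.7], 1.3
        params = RunParams(kappa=kappa)
        liouv = build_liouvillian(h, [attach[0]], [attach[1]], params,
                                  eta_per_sink=etas)
        rho = rng.normal(size=(6, 6)) + 1j * rng.normal(size=(6, 6))
        rho = (rho + rho.conj().T) / 2
        np.testing.assert_allclose(
            apply_generator(liouv, rho),
            dense_generator_action(h, attach, etas, kappa, rho),
            atol=1e-12,
        )

    def test_non_hermitian_rejected(self):
        with pytest.raises(ValidationError):
            build_liouvillian(np.array([[0.0, 1.0], [0.0, 0.0]]), [], [], RunParams())


class TestClosedForms:
    def test_single_node_sink_decay(self):
        params = RunParams(kappa=0.0, eta_sink=1.0, dt=0.05, t_end=10.0)
        liouv = build_liouvillian(np.zeros((1, 1)), [0], [], params)
        trace = propagate_gksl(liouv, initial_state(1, [0], 1), params)
        np.testing.assert_allclose(trace.target_absorption,
                                   1 - np.exp(-trace.times), atol=1e-6)
        p_t, p_d = absorption_readout(trace)
        assert abs(p_t - (1 - np.exp(-10.0))) < 1e-6
        assert p_d == 0.0

    def test_two_site_rabi_oscillation(self):
        h = np.array([[-1.0, 1.0], [1.0, -1.0]])  # coupling J = 1
        params = RunParams(kappa=0.0, dt=0.05, t_end=10.0)
        liouv = build_liouvillian(h, [], [], params)
        trace = propagate_gksl(liouv, initial_state(2, [0], 0), params)
        np.testing.assert_allclose(trace.site_populations[:, 1],
                                   np.sin(trace.times) ** 2, atol=1e-6)

    def test_dephasing_decay_of_coherence_exact(self):
        kappa = 1.7
        params = RunParams(kappa=kappa, dt=0.1, t_end=3.0)
        liouv = build_liouvillian(np.zeros((2, 2)), [], [], params)
        trace = propagate_gksl(liouv, initial_state(2, [0, 1], 0, coherent=True),
                               params, keep_states=True)
        coher = np.abs(trace.states[:, 0, 1])
        np.testing.assert_allclose(coher, 0.5 * np.exp(-kappa * trace.times), atol=1e-10)

    @pytest.mark.parametrize("delta", [0.0, 5.0])
    def test_strong_dephasing_lorentzian_hopping_rate(self, delta):
        """At kappa >> J the coherent dynamics reduce to classical hopping at
        the adiabatic-elimination rate 2 J^2 kappa / (kappa^2 + Delta^2)."""
        j_coup, kappa = 1.0, 50.0
        h = np.array([[0.0, j_coup], [j_coup, delta]])
        params = RunParams(kappa=kappa, dt=0.5, t_end=25.0)
        liouv = build_liouvillian(h, [], [], params)
        trace = propagate_gksl(liouv, initial_state(2, [0], 0), params)
        p2 = trace.site_populations[:, 1]
        # p2(t) = (1 - exp(-2 R t)) / 2  =>  fit R from log(1 - 2 p2)
        mask = (trace.times > 0) & (1 - 2 * p2 > 1e-3)
        slope = np.polyfit(trace.times[mask], np.log(1 - 2 * p2[mask]), 1)[0]
        rate_fit = -slope / 2
        rate_theory = 2 * j_coup**2 * kappa / (kappa**2 + delta**2)
        assert abs(rate_fit - rate_theory) / rate_theory < 0.02

    def test_no_sinks_reads_zero_absorption(self):
        params = RunParams(kappa=1.0, dt=0.5, t_end=2.0)
        liouv = build_liouvillian(np.zeros((2, 2)), [], [], params)
        trace = propagate_gksl(liouv, initial_state(2, [0], 0), params)
        assert absorption_readout(trace) == (0.0, 0.0)


class TestStateProperties:
    def test_conservation_and_positivity_random_instances(self, rng):
        for _ in range(20):
            graph, roles, kappa, epsilon = random_instance(rng)
            ham = HamiltonianSpec()
            w = symmetrize_coupling(graph, ham)
            h = build_hamiltonian(build_laplacian(w), ham,
                                  rng.uniform(-epsilon, epsilon, graph.n_nodes))
            t_idx = graph.indices_of(roles.target_sinks)
            d_idx = graph.indices_of(roles.distractor_sinks)
            params = RunParams(kappa=kappa, dt=1.0, t_end=5.0)
            liouv = build_liouvillian(h, t_idx, d_idx, params)
            s0 = initial_state(graph.n_nodes, graph.indices_of(roles.source_nodes),
                               liouv.n_sinks)
            trace = propagate_gksl(liouv, s0, params, keep_states=True)
            totals = trace.site_populations.sum(axis=1) + trace.sink_populations.sum(axis=1)
            np.testing.assert_allclose(totals, 1.0, atol=1e-6)
            for state in trace.states:
                assert np.linalg.eigvalsh(state).min() >= -1e-8
            assert np.all(np.diff(trace.target_absorption) >= -1e-10)
            assert np.all(np.diff(trace.distractor_absorption) >= -1e-10)

    def test_zero_dephasing_preserves_conditional_purity(self):
        """With kappa=0 and sinks active, a pure initial state keeps a rank-1
        graph block (non-Hermitian effective evolution preserves purity)."""
        h = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
        params = RunParams(kappa=0.0, dt=0.5, t_end=4.0)
        liouv = build_liouvillian(h, [2], [], params)
        trace = propagate_gksl(liouv, initial_state(3, [0], 1, coherent=True),
                               params, keep_states=True)
        for state in trace.states:
            evals = np.sort(np.linalg.eigvalsh(state[:3, :3]))
            assert np.abs(evals[:-1]).max() <= 1e-8


def test_simulate_run_engine_dispatch(two_site):
    graph, roles, _ = two_site
    p_t, p_d = simulate_run(graph, roles, "gksl", 0.5, 0.0, 0,
                            HamiltonianSpec(), RunParams(kappa=0.5, dt=0.5, t_end=5.0))
    assert 0 < p_t <= 1 and p_d == 0.0
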