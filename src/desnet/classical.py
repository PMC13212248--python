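"""Classical competitor dynamics sharing the sink/readout contract.

Two baselines are provided:

* CRW — a continuous-time random walk whose hop rate ``u -> v`` is
  ``gamma * W_sym[u, v]`` on the same symmetrized coupling as the
  open-system Hamiltonian, so the matched baseline differs only in
  dynamics, not topology.
* CRW_thermal — thermally activated Metropolis hopping at temperature
  ``t_env``: ``rate(u -> v) = gamma * W_sym[u, v] * min(1, exp(-(E_v - E_u)/t_env))``,
  which satisfies detailed balance with respect to Boltzmann weights
  ``exp(-E_u / t_env)`` on the sink-free graph.

A Lorentzian-rate generator, ``2 |H_uv|^2 kappa / (kappa^2 + Delta_uv^2)``,
is also provided: it is the strong-dephasing classical limit of the GKSL
dynamics and serves as the cross-engine equivalence check.

Sinks leak attachment-node mass into absorber entries at rate ``eta_sink``;
generators are column-stochastic (columns sum to zero) so total mass on the
augmented space is conserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.sparse.linalg import expm_multiply

from .errors import PropagationError, require
from .trace import PropagationTrace

__all__ = [
    "ClassicalRateModel",
    "build_crw_generator",
    "build_thermal_generator",
    "build_lorentzian_generator",
    "propagate_classical",
]


@dataclass
class ClassicalRateModel:
    """Column-stochastic rate matrix on graph nodes plus sink absorbers.

    ``generator[v, u]`` is the rate of the jump ``u -> v`` for ``u != v``;
    diagonal entries make every column sum to zero.
    """

    generator: np.ndarray
    n_nodes: int
    target_idx: np.ndarray
    distractor_idx: np.ndarray
    t_env: float | None = None

    def __post_init__(self):
        q = np.asarray(self.generator, dtype=float)
        off = q - np.diag(np.diag(q))
        require(bool(np.all(off >= -1e-12)), "off-diagonal rates must be nonnegative")
        require(bool(np.all(np.abs(q.sum(axis=0)) < 1e-9)), "columns must sum to zero")
        self.generator = q

    @property
    def n_sinks(self) -> int:
        return len(self.target_idx) + len(self.distractor_idx)

    @property
    def dim(self) -> int:
        return self.generator.shape[0]


def _assemble(
    rates: np.ndarray,
    target_idx: Sequence[int],
    distractor_idx: Sequence[int],
    eta_sink: float,
    t_env: float | None,
) -> ClassicalRateModel:
    n = rates.shape[0]
    target_idx = np.asarray(list(target_idx), dtype=int)
    distractor_idx = np.asarray(list(distractor_idx), dtype=int)
    attach = np.concatenate([target_idx, distractor_idx]) if (len(target_idx) + len(distractor_idx)) else np.array([], dtype=int)
    n_sinks = len(attach)
    m = n + n_sinks
    q = np.zeros((m, m))
    q[:n, :n] = rates.T  # rate u->v goes to entry (v, u)
    np.fill_diagonal(q[:n, :n], 0.0)
    for s, a in enumerate(attach):
        q[n + s, a] = eta_sink
    q -= np.diag(q.sum(axis=0))
    return ClassicalRateModel(
        generator=q, n_nodes=n, target_idx=target_idx, distractor_idx=distractor_idx, t_env=t_env
    )


def build_crw_generator(
    w_sym: np.ndarray,
    gamma: float,
    target_idx: Sequence[int],
    distractor_idx: Sequence[int],
    eta_sink: float = 1.0,
) -> ClassicalRateModel:
    """Continuous-time random walk with hop rates ``gamma * W_sym``."""
    w_sym = np.asarray(w_sym, dtype=float)
    require(np.allclose(w_sym, w_sym.T, atol=1e-12), "coupling matrix must be symmetric")
    require(gamma > 0, "gamma must be positive")
    return _assemble(gamma * w_sym, target_idx, distractor_idx, eta_sink, t_env=None)


def build_thermal_generator(
    w_sym: np.ndarray,
    gamma: float,
    energies: np.ndarray,
    target_idx: Sequence[int],
    distractor_idx: Sequence[int],
    eta_sink: float = 1.0,
    t_env: float = 0.1,
) -> ClassicalRateModel:
    """Metropolis hopping: uphill moves suppressed by ``exp(-dE / t_env)``."""
    require(t_env > 0, "t_env must be positive")
    w_sym = np.asarray(w_sym, dtype=float)
    require(np.allclose(w_sym, w_sym.T, atol=1e-12), "coupling matrix must be symmetric")
    energies = np.asarray(energies, dtype=float)
    require(energies.shape == (w_sym.shape[0],), "energy vector length mismatch")
    de = energies[None, :] - energies[:, None]  # E_v - E_u for move u -> v
    metro = np.minimum(1.0, np.exp(-de / t_env))
    return _assemble(gamma * w_sym * metro, target_idx, distractor_idx, eta_sink, t_env=t_env)


def build_lorentzian_generator(
    hamiltonian: np.ndarray,
    kappa: float,
    target_idx: Sequence[int],
    distractor_idx: Sequence[int],
    eta_sink: float = 1.0,
) -> ClassicalRateModel:
    """Strong-dephasing classical limit: rates ``2|H_uv|^2 kappa / (kappa^2 + Delta_uv^2)``
    with detuning ``Delta_uv = H_vv - H_uu``."""
    h = np.asarray(hamiltonian, dtype=float)
    require(kappa > 0, "kappa must be positive")
    require(np.allclose(h, h.T, atol=1e-10), "Hamiltonian must be symmetric")
    site_e = np.diag(h)
    delta = site_e[None, :] - site_e[:, None]
    rates = 2.0 * h**2 * kappa / (kappa**2 + delta**2)
    np.fill_diagonal(rates, 0.0)
    return _assemble(rates, target_idx, distractor_idx, eta_sink, t_env=None)


def propagate_classical(
    model: ClassicalRateModel,
    p0: np.ndarray,
    dt: float,
    t_end: float,
) -> PropagationTrace:
    """Evolve ``p(t) = exp(t Q) p0`` on the grid ``0, dt, ..., t_end``."""
    require(0 < dt <= t_end, "need 0 < dt <= t_end")
    p0 = np.asarray(p0, dtype=float)
    m = model.dim
    require(p0.shape == (m,), f"initial vector must have length {m}")
    require(bool(np.all(p0 >= -1e-12)) and abs(p0.sum() - 1.0) < 1e-9, "p0 must be a probability vector")

    n_steps = int(round(t_end / dt))
    times = np.linspace(0.0, t_end, n_steps + 1)
    if len(times) == 1:
        sol = p0[None, :]
    else:
        sol = expm_multiply(model.generator, p0, start=0.0, stop=float(times[-1]), num=len(times), endpoint=True)
    if not np.all(np.isfinite(sol)):
        bad = int(np.argmax(~np.isfinite(sol).all(axis=1)))
        raise PropagationError(f"non-finite state at t={times[bad]:g}", t_fail=float(times[bad]))
    total = sol.sum(axis=1)
    if np.max(np.abs(total - 1.0)) > 1e-8:
        bad = int(np.argmax(np.abs(total - 1.0) > 1e-8))
        raise PropagationError(
            f"mass conservation violated at t={times[bad]:g}", t_fail=float(times[bad])
        )

    n = model.n_nodes
    n_t = len(model.target_idx)
    sink_pop = sol[:, n:]
    return PropagationTrace(
        times=times,
        site_populations=sol[:, :n],
        sink_populations=sink_pop,
        target_absorption=sink_pop[:, :n_t].sum(axis=1),
        distractor_absorption=sink_pop[:, n_t:].sum(axis=1),
        engine="classical",
        states=None,
    )
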