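"""Factorial sweep orchestration over kappa x epsilon x variant.

Ensemble design: the native variant runs ``n_trials`` independent disorder
draws per (kappa, epsilon) cell; surrogate variants (type-aware rewiring,
pathway lesioning) run ``n_surrogates`` surrogate graphs, each over the
same ``n_trials`` draws (``n_surrogates * n_trials`` runs per cell).
Disorder seeds are shared across variants and engines at equal
(kappa, epsilon, trial) so cross-variant contrasts are paired.

Seeding is counter-based: every random draw is a pure function of
(base_seed, role tag, indices), so execution order and parallelism cannot
change results, and any single cell re-run in isolation reproduces the
corresponding rows of a full sweep exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .classical import build_crw_generator, build_thermal_generator, propagate_classical
from .errors import PropagationError, require
from .gksl import RunParams, build_liouvillian, initial_state, propagate_gksl
from .graph import (
    ConnectomeGraph,
    DisorderSpec,
    HamiltonianSpec,
    RoleAssignment,
    build_hamiltonian,
    build_laplacian,
    draw_disorder,
    symmetrize_coupling,
)
from .metrics import MetricsConfig, RunRecord, end_metrics, p_good, sel_rom
from .surrogates import SurrogateSpec, lesion_edges, rewire_type_preserving
from .trace import absorption_readout

__all__ = ["SweepConfig", "SweepTable", "run_condition", "run_benchmark_sweep", "summarize_cells"]

logger = logging.getLogger(__name__)

_DISORDER_TAG = 101
_SURROGATE_TAG = 202


def derive_seed(*parts: int) -> int:
    """Pure counter-based seed derivation; stable across platforms, < 2^31."""
    ss = np.random.SeedSequence([int(p) for p in parts])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


@dataclass(frozen=True)
class SweepConfig:
    """Grids, ensemble sizes and engine choice for a benchmark sweep."""

    kappa_grid: tuple[float, ...] = (0.001, 1.0, 3.0, 10.0)
    epsilon_grid: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 5.0)
    variants: tuple[str, ...] = ("original", "rewired_type", "lesion_KC_MBON")
    n_trials: int = 20
    n_surrogates: int = 20
    engine: str = "gksl"  # "gksl" | "crw" | "crw_thermal"
    base_seed: int = 0
    substrate: str = "unnamed"
    t_env: float = 0.1  # temperature of the thermal baseline
    coherent_init: bool = False
    ham_spec: HamiltonianSpec | None = None  # default: row-normalize iff graph is directed
    run_params: RunParams = field(default_factory=RunParams)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    surrogate: SurrogateSpec = field(default_factory=SurrogateSpec)

    def __post_init__(self):
        require(len(self.kappa_grid) > 0 and len(self.epsilon_grid) > 0, "grids must be nonempty")
        require(self.n_trials >= 1 and self.n_surrogates >= 1, "ensemble sizes must be >= 1")
        require(self.engine in ("gksl", "crw", "crw_thermal"), f"unknown engine {self.engine!r}")

    def expected_records(self) -> int:
        per_cell = 0
        for v in self.variants:
            per_cell += self.n_trials if v == "original" else self.n_surrogates * self.n_trials
        return per_cell * len(self.kappa_grid) * len(self.epsilon_grid)


@dataclass
class SweepTable:
    """Long-format collection of run records plus provenance."""

    records: pd.DataFrame
    config: SweepConfig
    graph_fingerprint: str
    n_failed: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def ok(self) -> pd.DataFrame:
        return self.records[self.records["status"] == "ok"]

    def summary(self, ci_resamples: int = 1000) -> pd.DataFrame:
        return summarize_cells(self, ci_resamples=ci_resamples)


def simulate_run(
    graph: ConnectomeGraph,
    roles: RoleAssignment,
    engine: str,
    kappa: float,
    epsilon: float,
    disorder_seed: int,
    ham_spec: HamiltonianSpec,
    run_params: RunParams,
    t_env: float = 0.1,
    coherent_init: bool = False,
) -> tuple[float, float]:
    """One propagation on one graph; returns (P_T, P_D) at the horizon."""
    roles.validate_against(graph)
    w_sym = symmetrize_coupling(graph, ham_spec)
    l_sym = build_laplacian(w_sym)
    energies = draw_disorder(graph.n_nodes, DisorderSpec(epsilon=epsilon, seed=disorder_seed))
    t_idx = graph.indices_of(roles.target_sinks)
    d_idx = graph.indices_of(roles.distractor_sinks)
    s_idx = graph.indices_of(roles.source_nodes)
    params = replace(run_params, kappa=kappa)

    if engine == "gksl":
        h = build_hamiltonian(l_sym, ham_spec, energies)
        liouv = build_liouvillian(h, t_idx, d_idx, params)
        state0 = initial_state(graph.n_nodes, s_idx, liouv.n_sinks, coherent=coherent_init)
        trace = propagate_gksl(liouv, state0, params)
    else:
        if engine == "crw":
            model = build_crw_generator(w_sym, ham_spec.gamma, t_idx, d_idx, params.eta_sink)
        else:
            model = build_thermal_generator(
                w_sym, ham_spec.gamma, energies, t_idx, d_idx, params.eta_sink, t_env=t_env
            )
        p0 = np.zeros(model.dim)
        p0[s_idx] = 1.0 / len(s_idx)
        trace = propagate_classical(model, p0, params.dt, params.t_end)
    return absorption_readout(trace)


def run_condition(
    graph: ConnectomeGraph,
    roles: RoleAssignment,
    engine: str,
    kappa: float,
    epsilon: float,
    n_trials: int,
    seed_for_trial: Callable[[int], int],
    ham_spec: HamiltonianSpec,
    run_params: RunParams,
    metrics_cfg: MetricsConfig = MetricsConfig(),
    t_env: float = 0.1,
    substrate: str = "unnamed",
    variant: str = "original",
    surrogate: int | None = None,
    coherent_init: bool = False,
) -> list[RunRecord]:
    """Run ``n_trials`` independent disorder draws of one (kappa, epsilon) cell.

    ``seed_for_trial(trial)`` supplies the disorder seed per trial.  A
    propagation failure flags the record as failed and the condition
    continues; the failure count is logged.
    """
    records: list[RunRecord] = []
    n_failed = 0
    for trial in range(n_trials):
        seed = seed_for_trial(trial)
        base = dict(
            substrate=substrate,
            variant=variant,
            engine=engine,
            kappa=kappa,
            epsilon=epsilon,
            trial=trial,
            seed=seed,
            surrogate=surrogate,
        )
        try:
            p_t, p_d = simulate_run(
                graph, roles, engine, kappa, epsilon, seed,
                ham_spec, run_params, t_env=t_env, coherent_init=coherent_init,
            )
            s, c, u, ipc = end_metrics(p_t, p_d, metrics_cfg)
            records.append(RunRecord(p_t=p_t, p_d=p_d, selectivity_end=s, coverage_end=c,
                                     utility=u, info_per_cost=ipc, status="ok", **base))
        except PropagationError as exc:
            n_failed += 1
            logger.warning("run failed (%s, kappa=%g, eps=%g, trial=%d): %s",
                           variant, kappa, epsilon, trial, exc)
            records.append(RunRecord(p_t=float("nan"), p_d=float("nan"),
                                     selectivity_end=float("nan"), coverage_end=float("nan"),
                                     utility=float("nan"), info_per_cost=float("nan"),
                                     status="failed", **base))
    if n_failed:
        logger.warning("%d/%d runs failed in condition (%s, kappa=%g, eps=%g)",
                       n_failed, n_trials, variant, kappa, epsilon)
    return records


def _variant_graphs(
    graph: ConnectomeGraph, config: SweepConfig, variant: str, variant_idx: int
) -> list[tuple[int | None, ConnectomeGraph]]:
    """Graphs to run for a variant: the native graph, or a surrogate ensemble."""
    if variant == "original":
        return [(None, graph)]
    if "rewired" in variant:
        kind = "rewired_type"
    elif "lesion" in variant:
        kind = "lesion"
    else:
        raise ValueError(f"cannot infer surrogate kind from variant label {variant!r}")
    out = []
    for s in range(config.n_surrogates):
        seed = derive_seed(config.base_seed, _SURROGATE_TAG, variant_idx, s)
        spec = replace(config.surrogate, kind=kind, seed=seed)
        g = rewire_type_preserving(graph, spec) if kind == "rewired_type" else lesion_edges(graph, spec)
        out.append((s, g))
    return out


def run_benchmark_sweep(
    graph: ConnectomeGraph, roles: RoleAssignment, config: SweepConfig
) -> SweepTable:
    """Full kappa x epsilon x variant factorial with ensemble bookkeeping."""
    roles.validate_against(graph)
    ham_spec = config.ham_spec or HamiltonianSpec(gamma=1.0, row_normalize=graph.directed)
    all_records: list[RunRecord] = []
    for v_idx, variant in enumerate(config.variants):
        for surrogate, g in _variant_graphs(graph, config, variant, v_idx):
            for k_idx, kappa in enumerate(config.kappa_grid):
                for e_idx, epsilon in enumerate(config.epsilon_grid):
                    # disorder seed omits variant/surrogate so contrasts are paired
                    seed_fn = lambda trial, k=k_idx, e=e_idx: derive_seed(
                        config.base_seed, _DISORDER_TAG, k, e, trial
                    )
                    all_records.extend(
                        run_condition(
                            g, roles, config.engine, kappa, epsilon, config.n_trials,
                            seed_fn, ham_spec, config.run_params, config.metrics,
                            t_env=config.t_env, substrate=config.substrate,
                            variant=variant, surrogate=surrogate,
                            coherent_init=config.coherent_init,
                        )
                    )
    df = pd.DataFrame([r.__dict__ for r in all_records])
    n_failed = int((df["status"] == "failed").sum())
    assert len(df) == config.expected_records()
    return SweepTable(records=df, config=config, graph_fingerprint=graph.fingerprint(),
                      n_failed=n_failed)


def summarize_cells(table: SweepTable, ci_resamples: int = 1000) -> pd.DataFrame:
    """Per-(variant, kappa, epsilon) summary of the readout metrics.

    Both selectivity aggregations are reported: the run-level mean of
    ratios and the ratio-of-means SelRoM, alongside mean coverage, P_good,
    and a percentile bootstrap CI on mean selectivity.
    """
    from .inference import bootstrap_ci

    require(len(table.records) > 0, "empty sweep table")
    df = table.ok()
    rows = []
    for (variant, kappa, epsilon), cell in df.groupby(["variant", "kappa", "epsilon"]):
        ci = (
            bootstrap_ci(cell["selectivity_end"].to_numpy(), np.mean,
                         n_resamples=ci_resamples,
                         seed=derive_seed(table.config.base_seed, 303))
            if len(cell) >= 2
            else None
        )
        rows.append(
            {
                "variant": variant,
                "kappa": kappa,
                "epsilon": epsilon,
                "n": len(cell),
                "selectivity_mean": float(cell["selectivity_end"].mean()),
                "sel_rom": sel_rom(cell, delta=table.config.metrics.delta),
                "coverage_mean": float(cell["coverage_end"].mean()),
                "p_good": p_good(cell, table.config.metrics),
                "selectivity_ci_low": ci.ci_low if ci else float("nan"),
                "selectivity_ci_high": ci.ci_high if ci else float("nan"),
            }
        )
    return pd.DataFrame(rows)
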