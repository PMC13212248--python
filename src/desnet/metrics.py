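"""Scalar readout metrics, ensemble aggregations, and the commitment-cost toy model.

All metrics are functions of the finite-horizon sink captures P_T and P_D:

    Selectivity_end = P_T / (P_D + delta)        delta = 1e-12 ratio guard
    coverage_end    = P_T + P_D                  throughput-proportional cost proxy
    Utility(lambda) = P_T - lambda * P_D
    InfoPerCost     = Utility / (coverage_end + chi)
    P_good          = Pr(Selectivity_end > S_thr  and  P_T > pT_min)

Two ensemble aggregations of selectivity are distinguished throughout:
the run-level mean of ratios, and the more conservative ratio of means
SelRoM = <P_T> / (<P_D> + delta).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import require

__all__ = [
    "MetricsConfig",
    "RunRecord",
    "end_metrics",
    "sel_rom",
    "p_good",
    "envelope_over_kappa",
    "expected_commit_cycles",
    "commit_energy_gain",
]


@dataclass(frozen=True)
class MetricsConfig:
    """Guards and thresholds for the readout metrics (all dimensionless)."""

    delta: float = 1e-12  # ratio guard in selectivity
    lam: float = 1.0  # distractor penalty in Utility
    chi: float = 0.01  # cost guard in InfoPerCost
    s_thr: float = 2.0  # good-run selectivity threshold
    pt_min: float = 0.005  # good-run absorption floor

    def __post_init__(self):
        require(self.delta > 0, "delta must be positive")
        require(self.chi > 0, "chi must be positive")


@dataclass
class RunRecord:
    """One simulation run: provenance plus readouts and derived metrics."""

    substrate: str
    variant: str
    engine: str
    kappa: float
    epsilon: float
    trial: int
    seed: int
    p_t: float
    p_d: float
    selectivity_end: float
    coverage_end: float
    utility: float
    info_per_cost: float
    surrogate: int | None = None  # absent for the native variant
    status: str = "ok"


def end_metrics(
    p_t: float, p_d: float, config: MetricsConfig = MetricsConfig()
) -> tuple[float, float, float, float]:
    """(selectivity_end, coverage_end, utility, info_per_cost) for one run."""
    require(0 <= p_t <= 1 and 0 <= p_d <= 1, f"P_T, P_D must lie in [0, 1]; got ({p_t}, {p_d})")
    selectivity = p_t / (p_d + config.delta)
    coverage = p_t + p_d
    utility = p_t - config.lam * p_d
    info_per_cost = utility / (coverage + config.chi)
    return selectivity, coverage, utility, info_per_cost


def _as_frame(records: Iterable[RunRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    rows = [r.__dict__ for r in records]
    return pd.DataFrame(rows)


def sel_rom(records: Iterable[RunRecord] | pd.DataFrame, delta: float = 1e-12) -> float:
    """Ratio-of-means selectivity SelRoM = mean(P_T) / (mean(P_D) + delta)."""
    df = _as_frame(records)
    require(len(df) > 0, "empty ensemble")
    return float(df["p_t"].mean() / (df["p_d"].mean() + delta))


def p_good(records: Iterable[RunRecord] | pd.DataFrame, config: MetricsConfig = MetricsConfig()) -> float:
    """Fraction of runs with selectivity above S_thr and absorption above pT_min."""
    df = _as_frame(records)
    require(len(df) > 0, "empty ensemble")
    ok = (df["selectivity_end"] > config.s_thr) & (df["p_t"] > config.pt_min)
    return float(ok.mean())


def envelope_over_kappa(
    sweep: pd.DataFrame, objective: str = "selectivity_end"
) -> pd.DataFrame:
    """Upper envelope over the dephasing grid at each disorder level.

    For each epsilon, the maximum over kappa of the cell-mean objective and
    the kappa achieving it (ties broken toward smaller kappa).  Expects a
    long-format table with ``kappa``, ``epsilon`` and the objective column;
    every (epsilon, kappa) cell present in the grid must be nonempty.
    """
    require(objective in sweep.columns, f"objective column {objective!r} missing")
    require(len(sweep) > 0, "empty sweep table")
    eps_levels = np.sort(sweep["epsilon"].unique())
    kap_levels = np.sort(sweep["kappa"].unique())
    cells = sweep.groupby(["epsilon", "kappa"])[objective].mean()
    missing = [
        (float(e), float(k))
        for e in eps_levels
        for k in kap_levels
        if (e, k) not in cells.index
    ]
    require(not missing, f"missing (epsilon, kappa) cells: {missing}")
    rows = []
    for e in eps_levels:
        by_k = cells.loc[e].reindex(kap_levels)
        best_k = by_k.index[np.argmax(by_k.values)]  # argmax returns first (smallest kappa) on ties
        rows.append({"epsilon": float(e), "best_kappa": float(best_k), objective: float(by_k.loc[best_k])})
    return pd.DataFrame(rows)


def expected_commit_cycles(p_t: float) -> float:
    """Expected number of commitment cycles under repeat-until-correct, 1 / P_T.

    ``P_T = 0`` yields ``math.inf`` (a sentinel, not an exception)."""
    require(p_t >= 0, "P_T must be nonnegative")
    return math.inf if p_t == 0 else 1.0 / p_t


@dataclass(frozen=True)
class CommitEnergyGain:
    """Net energy gain of pre-selection under the two-stage cost accounting."""

    cycles_before: float
    cycles_after: float
    delta_e: float
    spike_cost_ratio: float = 35.0  # C_spike = r * C_local working value


def commit_energy_gain(
    p_t_before: float,
    p_t_after: float,
    e_commit: float,
    e_netting: float,
    spike_cost_ratio: float = 35.0,
) -> CommitEnergyGain:
    """Energy accounting for a pre-selection gain in target absorption.

    With expected commitment counts ``1/P_T``, improving absorption from
    ``p_t_before`` to ``p_t_after`` saves
    ``delta_E = (1/P_T_before - 1/P_T_after) * E_II - E_I``
    where ``E_II`` is the marginal cost of one commitment event and ``E_I``
    the pre-selection overhead.  An alpha-fold increase in P_T reduces the
    expected cycle count by exactly alpha.
    """
    n_before = expected_commit_cycles(p_t_before)
    n_after = expected_commit_cycles(p_t_after)
    delta_e = (n_before - n_after) * e_commit - e_netting
    return CommitEnergyGain(
        cycles_before=n_before,
        cycles_after=n_after,
        delta_e=delta_e,
        spike_cost_ratio=spike_cost_ratio,
    )
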