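"""Resampling and ANOVA inference for sweep ensembles.

Three tools establish the disorder-enhanced-selectivity (DES) evidence:

* percentile bootstrap confidence intervals over runs (default B = 5000),
* a distribution-free Monte-Carlo permutation test for the pre-specified
  contrast between a high-disorder and a zero-disorder group (one-sided
  "greater" by default, +1-corrected p so sampled permutations never
  report p = 0),
* cell-means ANOVA on run-level responses: each effect row is its own
  cell-means fit (one-way on VARIANT, one-way on EPSILON, and the full
  VARIANT x EPSILON cell structure), reported with F, degrees of freedom,
  p, and partial eta squared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import require

__all__ = [
    "BootstrapResult",
    "PermutationResult",
    "AnovaTable",
    "InferenceReport",
    "bootstrap_ci",
    "permutation_contrast",
    "two_way_anova",
    "analyze_des",
]


@dataclass(frozen=True)
class BootstrapResult:
    point_estimate: float
    ci_low: float
    ci_high: float
    n_resamples: int
    seed: int

    def __post_init__(self):
        require(self.ci_low <= self.ci_high + 1e-15, "ci_low must not exceed ci_high")


@dataclass(frozen=True)
class PermutationResult:
    delta_obs: float
    p_perm: float
    n_permutations: int
    sidedness: str

    def __post_init__(self):
        require(0 < self.p_perm <= 1, "permutation p must lie in (0, 1]")


@dataclass
class AnovaTable:
    """Per-effect F statistics; `frame` holds one row per effect."""

    frame: pd.DataFrame

    def __getitem__(self, effect: str) -> pd.Series:
        return self.frame.set_index("effect").loc[effect]


def bootstrap_ci(
    values: Sequence[float] | tuple[Sequence[float], Sequence[float]],
    statistic: Callable[..., float] = np.mean,
    n_resamples: int = 5000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> BootstrapResult:
    """Percentile bootstrap CI for a statistic of one sample or two paired samples.

    Paired samples (a 2-tuple of equal-length arrays) are resampled jointly
    by run index and the statistic is called as ``statistic(a, b)``.
    Vectorized statistics (accepting ``axis=``) are exploited when possible;
    otherwise each resample is evaluated individually.
    """
    if n_resamples < 100:
        warnings.warn(f"n_resamples={n_resamples} is very small for a percentile CI")
    paired = isinstance(values, tuple) and len(values) == 2 and not np.isscalar(values[0])
    rng = np.random.default_rng(seed)

    if paired:
        a = np.asarray(values[0], dtype=float)
        b = np.asarray(values[1], dtype=float)
        require(a.shape == b.shape and a.ndim == 1, "paired samples must be equal-length vectors")
        n = len(a)
        require(n >= 2, "sample size must be at least 2")
        point = float(statistic(a, b))
        idx = rng.integers(0, n, size=(n_resamples, n))
        try:
            boots = np.asarray(statistic(a[idx], b[idx], axis=1), dtype=float)
            if boots.shape != (n_resamples,):
                raise TypeError
        except TypeError:
            boots = np.array([statistic(a[row], b[row]) for row in idx])
    else:
        x = np.asarray(values, dtype=float)
        require(x.ndim == 1, "sample must be one-dimensional")
        n = len(x)
        require(n >= 2, "sample size must be at least 2")
        point = float(statistic(x))
        idx = rng.integers(0, n, size=(n_resamples, n))
        try:
            boots = np.asarray(statistic(x[idx], axis=1), dtype=float)
            if boots.shape != (n_resamples,):
                raise TypeError
        except TypeError:
            boots = np.array([statistic(x[row]) for row in idx])

    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return BootstrapResult(
        point_estimate=point,
        ci_low=float(lo),
        ci_high=float(hi),
        n_resamples=n_resamples,
        seed=seed,
    )


def permutation_contrast(
    group_hi: Sequence[float],
    group_lo: Sequence[float],
    n_permutations: int = 10_000,
    seed: int = 0,
    sidedness: str = "greater",
) -> PermutationResult:
    """Monte-Carlo permutation test on the difference of group means.

    ``delta_obs = mean(group_hi) - mean(group_lo)``; labels are permuted
    ``n_permutations`` times and the +1-corrected p-value is
    ``(1 + #{delta* >= delta_obs}) / (1 + n_permutations)`` for the
    one-sided "greater" default (absolute values for "two-sided").
    """
    require(sidedness in ("greater", "less", "two-sided"), f"unknown sidedness {sidedness!r}")
    hi = np.asarray(group_hi, dtype=float)
    lo = np.asarray(group_lo, dtype=float)
    require(hi.size > 0 and lo.size > 0, "both groups must be nonempty")
    require(hi.size + lo.size >= 4, "need at least 4 observations in total")

    delta_obs = float(hi.mean() - lo.mean())
    pooled = np.concatenate([hi, lo])
    n_hi = hi.size
    n_tot = pooled.size
    rng = np.random.default_rng(seed)

    # vectorized label permutation: argsort of uniforms is a random permutation
    u = rng.random((n_permutations, n_tot))
    order = np.argsort(u, axis=1)
    permuted = pooled[order]
    mean_hi = permuted[:, :n_hi].mean(axis=1)
    mean_lo = permuted[:, n_hi:].mean(axis=1)
    deltas = mean_hi - mean_lo

    if sidedness == "greater":
        extreme = np.count_nonzero(deltas >= delta_obs)
    elif sidedness == "less":
        extreme = np.count_nonzero(deltas <= delta_obs)
    else:
        extreme = np.count_nonzero(np.abs(deltas) >= abs(delta_obs))
    p = (1 + extreme) / (1 + n_permutations)
    return PermutationResult(
        delta_obs=delta_obs, p_perm=float(p), n_permutations=n_permutations, sidedness=sidedness
    )


def _one_way_ss(response: np.ndarray, groups: np.ndarray) -> tuple[float, float, int]:
    """(SS_effect, SS_residual, n_levels) from an OLS cell-means fit."""
    import statsmodels.formula.api as smf

    data = pd.DataFrame({"y": response, "g": groups})
    fit = smf.ols("y ~ C(g)", data=data).fit()
    return float(fit.ess), float(fit.ssr), int(data["g"].nunique())


def two_way_anova(
    records: pd.DataFrame,
    response: str = "selectivity_end",
    variant_col: str = "variant",
    epsilon_col: str = "epsilon",
) -> AnovaTable:
    """Run-level ANOVA over the variant x disorder factorial.

    Three effects are reported, each from its own cell-means fit so the
    degrees of freedom follow the cell counts directly: VARIANT (levels-1),
    EPSILON (levels-1), and VARIANT x EPSILON, the full cell-means model
    over all (variant, epsilon) cells (cells-1 numerator df).  Partial eta
    squared is SS_eff / (SS_eff + SS_res) per fit.
    """
    require(response in records.columns, f"response column {response!r} missing")
    df = records
    y = df[response].to_numpy(dtype=float)
    v = df[variant_col].to_numpy()
    e = df[epsilon_col].to_numpy()
    require(len(pd.unique(v)) >= 2, "need at least 2 variant levels")
    require(len(pd.unique(e)) >= 2, "need at least 2 epsilon levels")
    cells = pd.DataFrame({"v": v, "e": e}).groupby(["v", "e"]).size()
    empty = [
        (vi, ei)
        for vi in pd.unique(v)
        for ei in pd.unique(e)
        if (vi, ei) not in cells.index
    ]
    require(not empty, f"empty (variant, epsilon) cells: {empty}")

    combined = np.array([f"{vi}|{ei}" for vi, ei in zip(v, e)])
    rows = []
    for effect, groups in (
        ("VARIANT", v),
        ("EPSILON", e.astype(str)),
        ("VARIANT x EPSILON", combined),
    ):
        ss_eff, ss_res, n_levels = _one_way_ss(y, np.asarray(groups))
        df1 = n_levels - 1
        df2 = len(y) - n_levels
        require(ss_res > 0, f"zero residual variance in the {effect} fit")
        f_stat = (ss_eff / df1) / (ss_res / df2)
        p_val = float(sps.f.sf(f_stat, df1, df2))
        rows.append(
            {
                "effect": effect,
                "F": float(f_stat),
                "df1": df1,
                "df2": df2,
                "p": p_val,
                "partial_eta_sq": float(ss_eff / (ss_eff + ss_res)),
                "ss_effect": ss_eff,
                "ss_residual": ss_res,
            }
        )
    return AnovaTable(frame=pd.DataFrame(rows))


@dataclass
class InferenceReport:
    """DES inference for one sweep: per-variant disorder contrasts, the
    permutation test on the native contrast, between-variant differences,
    and ANOVA tables for selectivity and coverage."""

    eps_hi: float
    eps_lo: float
    kappa: float
    des_delta: dict  # variant -> BootstrapResult over paired per-trial deltas
    permutation: dict  # variant -> PermutationResult
    delta_des_between: dict  # (variant_a, variant_b) -> (BootstrapResult, p_boot)
    anova: dict  # response -> AnovaTable
    seed: int = 0

    def to_dict(self) -> dict:
        out = {
            "eps_hi": self.eps_hi,
            "eps_lo": self.eps_lo,
            "kappa": self.kappa,
            "seed": self.seed,
            "des_delta": {
                v: {"point": r.point_estimate, "ci_low": r.ci_low, "ci_high": r.ci_high,
                    "n_resamples": r.n_resamples}
                for v, r in self.des_delta.items()
            },
            "permutation": {
                v: {"delta_obs": r.delta_obs, "p_perm": r.p_perm,
                    "n_permutations": r.n_permutations, "sidedness": r.sidedness}
                for v, r in self.permutation.items()
            },
            "delta_des_between": {
                f"{a}-vs-{b}": {"point": r.point_estimate, "ci_low": r.ci_low,
                                "ci_high": r.ci_high, "p_boot": p}
                for (a, b), (r, p) in self.delta_des_between.items()
            },
            "anova": {resp: t.frame.to_dict(orient="records") for resp, t in self.anova.items()},
        }
        return out


def _paired_deltas(
    df: pd.DataFrame, eps_hi: float, eps_lo: float, response: str
) -> np.ndarray:
    """Per-(surrogate, trial) response difference between the two disorder levels.

    Pairing relies on disorder seeds being shared across epsilon-matched
    trial indices within a variant."""
    key = ["surrogate", "trial"]
    hi = df[df["epsilon"] == eps_hi].set_index(key)[response]
    lo = df[df["epsilon"] == eps_lo].set_index(key)[response]
    joined = pd.concat({"hi": hi, "lo": lo}, axis=1).dropna()
    require(len(joined) > 0, "no paired trials between the two epsilon levels")
    return (joined["hi"] - joined["lo"]).to_numpy(dtype=float)


def analyze_des(
    records: pd.DataFrame,
    eps_hi: float = 3.0,
    eps_lo: float = 0.0,
    kappa: float | None = None,
    response: str = "selectivity_end",
    native_variant: str = "original",
    n_resamples: int = 5000,
    n_permutations: int = 10_000,
    seed: int = 0,
    sidedness: str = "greater",
) -> InferenceReport:
    """Disorder-enhanced-selectivity inference on a long-format run table.

    For each variant: the paired per-trial contrast
    ``delta = response(eps_hi) - response(eps_lo)`` with a percentile
    bootstrap CI on its mean, and a Monte-Carlo permutation test of the
    group contrast.  Between-variant DES differences resample the native
    trials and the surrogate (surrogate, trial) pairs independently.
    ANOVA tables over the full variant x epsilon factorial are attached
    for selectivity and coverage when more than one variant is present.
    """
    df = records[records["status"] == "ok"] if "status" in records.columns else records
    if kappa is not None:
        df = df[np.isclose(df["kappa"], kappa)]
    require(len(df) > 0, "no records at the requested kappa")
    if "kappa" in df.columns:
        require(
            df["kappa"].nunique() == 1,
            "records span multiple kappa levels; pass kappa= to select one",
        )
    if "surrogate" not in df.columns:
        df = df.assign(surrogate=None)
    df = df.copy()
    df["surrogate"] = pd.to_numeric(df["surrogate"], errors="coerce").fillna(-1).astype(int)

    variants = list(pd.unique(df["variant"]))
    des_delta: dict = {}
    permutation: dict = {}
    deltas_by_variant: dict[str, np.ndarray] = {}
    for i, variant in enumerate(variants):
        sub = df[df["variant"] == variant]
        deltas = _paired_deltas(sub, eps_hi, eps_lo, response)
        deltas_by_variant[variant] = deltas
        des_delta[variant] = bootstrap_ci(
            deltas, np.mean, n_resamples=n_resamples, seed=seed + 11 * (i + 1)
        )
        permutation[variant] = permutation_contrast(
            sub[sub["epsilon"] == eps_hi][response].to_numpy(),
            sub[sub["epsilon"] == eps_lo][response].to_numpy(),
            n_permutations=n_permutations,
            seed=seed + 17 * (i + 1),
            sidedness=sidedness,
        )

    delta_des_between: dict = {}
    rng = np.random.default_rng(seed + 23)
    if native_variant in deltas_by_variant:
        for variant in variants:
            if variant == native_variant:
                continue
            a = deltas_by_variant[native_variant]
            b = deltas_by_variant[variant]
            point = float(a.mean() - b.mean())
            idx_a = rng.integers(0, len(a), size=(n_resamples, len(a)))
            idx_b = rng.integers(0, len(b), size=(n_resamples, len(b)))
            boots = a[idx_a].mean(axis=1) - b[idx_b].mean(axis=1)
            lo_q, hi_q = np.quantile(boots, [0.025, 0.975])
            p_boot = float((1 + np.count_nonzero(boots <= 0)) / (1 + n_resamples))
            delta_des_between[(native_variant, variant)] = (
                BootstrapResult(point_estimate=point, ci_low=float(lo_q), ci_high=float(hi_q),
                                n_resamples=n_resamples, seed=seed + 23),
                p_boot,
            )

    anova: dict = {}
    if len(variants) >= 2 and df["epsilon"].nunique() >= 2:
        for resp in ("selectivity_end", "coverage_end"):
            if resp in df.columns:
                anova[resp] = two_way_anova(df, response=resp)

    return InferenceReport(
        eps_hi=eps_hi, eps_lo=eps_lo,
        kappa=float(kappa) if kappa is not None else float("nan"),
        des_delta=des_delta, permutation=permutation,
        delta_des_between=delta_des_between, anova=anova, seed=seed,
    )
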