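import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from desnet import (
    ValidationError,
    analyze_des,
    bootstrap_ci,
    permutation_contrast,
    two_way_anova,
)


def oracle_one_way_ss(y, groups):
    """Direct sums-of-squares decomposition, independent of the OLS path."""
    y = np.asarray(y, dtype=float)
    grand = y.mean()
    ss_eff = ss_res = 0.0
    for g in np.unique(groups):
        sel = y[np.asarray(groups) == g]
        ss_eff += len(sel) * (sel.mean() - grand) ** 2
        ss_res += ((sel - sel.mean()) ** 2).sum()
    return ss_eff, ss_res


class TestBootstrap:
    def test_constant_sample_zero_width(self):
        res = bootstrap_ci(np.full(20, 3.3), np.mean, n_resamples=500, seed=1)
        assert res.ci_low == res.ci_high == pytest.approx(3.3)

    def test_gaussian_ci_width_close_to_analytic(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=10_000)
        res = bootstrap_ci(x, np.mean, n_resamples=5000, seed=2)
        width = res.ci_high - res.ci_low
        analytic = 2 * 1.96 / np.sqrt(len(x))
        assert abs(width - analytic) / analytic < 0.15

    def test_seed_reproducible_bit_for_bit(self):
        x = np.random.default_rng(3).normal(size=40)
        a = bootstrap_ci(x, np.mean, n_resamples=800, seed=7)
        b = bootstrap_ci(x, np.mean, n_resamples=800, seed=7)
        assert (a.ci_low, a.ci_high, a.point_estimate) == (b.ci_low, b.ci_high, b.point_estimate)

    def test_paired_resampling_of_difference(self):
        rng = np.random.default_rng(8)
        a = rng.normal(1.0, 0.1, size=60)
        b = a - 0.5 + rng.normal(0, 0.01, size=60)  # tightly paired
        res = bootstrap_ci((a, b), lambda x, y, axis=None: np.mean(x - y, axis=axis),
                           n_resamples=2000, seed=4)
        assert 0.45 < res.ci_low <= res.ci_high < 0.55

    def test_small_b_warns(self):
        with pytest.warns(UserWarning):
            bootstrap_ci(np.arange(10.0), np.mean, n_resamples=50, seed=0)

    def test_loop_fallback_for_non_vectorized_statistic(self):
        x = np.random.default_rng(9).normal(size=30)
        res = bootstrap_ci(x, lambda v: float(np.median(v)), n_resamples=300, seed=5)
        assert res.ci_low <= res.point_estimate <= res.ci_high


class TestPermutation:
    def test_identical_groups_null_p(self):
        x = np.random.default_rng(1).normal(size=30)
        res = permutation_contrast(x, x.copy(), n_permutations=10_000, seed=2)
        assert res.delta_obs == 0.0
        assert 0.4 <= res.p_perm <= 0.6

    def test_maximal_separation_attains_floor(self):
        lo = np.random.default_rng(2).normal(0, 0.01, size=20)
        hi = lo + 10
        n_perm = 2000
        res = permutation_contrast(hi, lo, n_permutations=n_perm, seed=3)
        assert res.p_perm == 1 / (n_perm + 1)

    def test_two_sided_detects_negative_shift(self):
        rng = np.random.default_rng(4)
        hi = rng.normal(-1.0, 0.1, size=15)
        lo = rng.normal(0.0, 0.1, size=15)
        one = permutation_contrast(hi, lo, n_permutations=2000, seed=5, sidedness="greater")
        two = permutation_contrast(hi, lo, n_permutations=2000, seed=5, sidedness="two-sided")
        assert one.p_perm > 0.9
        assert two.p_perm < 0.01

    def test_tiny_total_sample_rejected(self):
        with pytest.raises(ValidationError):
            permutation_contrast([1.0], [2.0, 3.0], n_permutations=100, seed=0)


class TestAnova:
    def test_balanced_design_matches_direct_ss_oracle(self):
        rng = np.random.default_rng(6)
        rows = []
        for v in ("x", "y"):
            for e in (0.0, 3.0):
                mu = {"x": 1.0, "y": 2.0}[v] + (0.5 if e else 0.0)
                for _ in range(25):
                    rows.append({"variant": v, "epsilon": e,
                                 "selectivity_end": mu + rng.normal(0, 0.3)})
        df = pd.DataFrame(rows)
        table = two_way_anova(df)
        y = df["selectivity_end"].to_numpy()
        for effect, groups in (
            ("VARIANT", df["variant"]),
            ("EPSILON", df["epsilon"].astype(str)),
            ("VARIANT x EPSILON", df["variant"] + "|" + df["epsilon"].astype(str)),
        ):
            ss_eff, ss_res = oracle_one_way_ss(y, groups.to_numpy())
            row = table[effect]
            df1, df2 = int(row["df1"]), int(row["df2"])
            f_oracle = (ss_eff / df1) / (ss_res / df2)
            assert abs(row["F"] - f_oracle) < 1e-8
            assert abs(row["partial_eta_sq"] - ss_eff / (ss_eff + ss_res)) < 1e-10
            assert abs(row["p"] - sps.f.sf(f_oracle, df1, df2)) < 1e-12
            # decomposition closes: SS_total = SS_effect + SS_residual
            ss_total = ((y - y.mean()) ** 2).sum()
            assert abs(ss_total - (ss_eff + ss_res)) / ss_total < 1e-6

    def test_null_factor_has_small_f(self):
        rng = np.random.default_rng(7)
        rows = []
        for v in ("x", "y"):
            for e in (0.0, 1.0, 3.0):
                for _ in range(30):
                    # response depends on epsilon only
                    rows.append({"variant": v, "epsilon": e,
                                 "selectivity_end": e + rng.normal(0, 0.05)})
        table = two_way_anova(pd.DataFrame(rows))
        assert table["VARIANT"]["F"] < 2.0
        assert table["EPSILON"]["F"] > 100.0

    def test_benchmark_design_degrees_of_freedom(self):
        """Cell sizes 20/400/400 per variant at 5 disorder levels give the
        benchmark dfs: 2/4097, 4/4095, and 14 with residual 4085."""
        rng = np.random.default_rng(8)
        rows = []
        for v, n_runs in (("original", 20), ("rewired_type", 400), ("lesion_KC_MBON", 400)):
            for e in (0.0, 1.0, 2.0, 3.0, 5.0):
                for _ in range(n_runs):
                    rows.append({"variant": v, "epsilon": e,
                                 "selectivity_end": rng.gamma(2.0, 1.0)})
        df = pd.DataFrame(rows)
        assert len(df) == 4100
        table = two_way_anova(df)
        assert (int(table["VARIANT"]["df1"]), int(table["VARIANT"]["df2"])) == (2, 4097)
        assert (int(table["EPSILON"]["df1"]), int(table["EPSILON"]["df2"])) == (4, 4095)
        assert (int(table["VARIANT x EPSILON"]["df1"]),
                int(table["VARIANT x EPSILON"]["df2"])) == (14, 4085)

    def test_empty_cell_rejected_with_location(self):
        df = pd.DataFrame({
            "variant": ["x", "x", "y"],
            "epsilon": [0.0, 3.0, 0.0],
            "selectivity_end": [1.0, 2.0, 3.0],
        })
        with pytest.raises(ValidationError, match="3.0"):
            two_way_anova(df)


class TestAnalyzeDes:
    def synthetic_table(self, des=1.0):
        rng = np.random.default_rng(11)
        rows = []
        for v, n_surr in (("original", None), ("rewired_type", 4)):
            surr_ids = [None] if n_surr is None else list(range(n_surr))
            for s in surr_ids:
                for e in (0.0, 3.0):
                    for t in range(12):
                        base = 1.0 + (des if (e == 3.0 and v == "original") else 0.0)
                        rows.append({
                            "variant": v, "surrogate": s, "kappa": 0.001,
                            "epsilon": e, "trial": t, "status": "ok",
                            "selectivity_end": base + rng.normal(0, 0.2),
                            "coverage_end": rng.uniform(0.2, 0.4),
                        })
        return pd.DataFrame(rows)

    def test_detects_planted_native_des(self):
        report = analyze_des(self.synthetic_table(des=1.0), n_resamples=1000,
                             n_permutations=2000, seed=3)
        native = report.permutation["original"]
        assert native.delta_obs > 0.5
        assert native.p_perm < 0.01
        boot = report.des_delta["original"]
        assert boot.ci_low > 0.5
        (between, p_boot) = report.delta_des_between[("original", "rewired_type")]
        assert between.ci_low > 0.0 and p_boot < 0.01

    def test_null_table_gives_nonsignificant_contrast(self):
        report = analyze_des(self.synthetic_table(des=0.0), n_resamples=500,
                             n_permutations=2000, seed=4)
        assert report.permutation["original"].p_perm > 0.05

    def test_report_serializes_to_plain_json_types(self):
        import json

        report = analyze_des(self.synthetic_table(), n_resamples=200,
                             n_permutations=500, seed=5)
        payload = json.dumps(report.to_dict())
        assert "p_perm" in payload and "anova" in payload

    def test_multiple_kappa_without_selection_rejected(self):
        df = self.synthetic_table()
        df2 = pd.concat([df, df.assign(kappa=1.0)])
        with pytest.raises(ValidationError):
            analyze_des(df2)
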