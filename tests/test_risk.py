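"""Risk metrics, group statistics, regressions, variance decomposition."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest

from hydrostand.pipeline import DEFAULT_TRUTH
from hydrostand.risk import (RiskSummary, across_model_range,
                             exceedance_fraction, failure_group_split,
                             group_comparison, relative_change_table,
                             stress_indicators, trait_regressions,
                             variance_decomposition)


class TestExceedance:
    def test_count_above_threshold(self):
        series = [0.7, 0.7, 0.7] + [0.1] * 7
        assert exceedance_fraction(series, 0.6) == pytest.approx(0.3)

    def test_all_below(self):
        assert exceedance_fraction([0.1, 0.2], 0.6) == 0.0

    def test_boundary_day_not_counted(self):
        # strict inequality: exactly 60% loss is not an exceedance
        assert exceedance_fraction([0.60, 0.60, 0.7, 0.1], 0.60) \
            == pytest.approx(0.25)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            exceedance_fraction([], 0.6)


class TestStressIndicators:
    def test_min_leaf_psi_constant_series(self, output_factory):
        out = output_factory(days=365, psi_leaf_min=-0.9)
        s = stress_indicators(out, DEFAULT_TRUTH)
        assert s.min_leaf_psi == pytest.approx(-0.9)

    def test_fraction_below_p50gs(self, output_factory):
        psi = np.full(8, -1.0)
        psi[:2] = DEFAULT_TRUTH.p50_gs - 0.5  # 2 of 8 days more negative
        out = output_factory(days=8, psi_leaf_min=psi)
        s = stress_indicators(out, DEFAULT_TRUTH)
        assert s.frac_days_below_p50gs == pytest.approx(0.25)

    def test_hydraulic_safety_margin_subtraction(self, output_factory):
        out = output_factory(days=30, psi_stem_min=-1.5)
        s = stress_indicators(out, DEFAULT_TRUTH)  # p50_stem = -3.0
        assert s.hsm == pytest.approx(-1.5 - DEFAULT_TRUTH.p50_stem)

    def test_threshold_monotonicity_invariant(self, output_factory):
        rng = np.random.default_rng(0)
        out = output_factory(days=200, plc_stem=rng.uniform(0, 1, 200))
        s = stress_indicators(out, DEFAULT_TRUTH)
        assert s.frac_days_plc80 <= s.frac_days_plc60

    def test_summary_invariants_enforced(self):
        with pytest.raises(ValueError, match="plc80"):
            RiskSummary(frac_days_plc60=0.1, frac_days_plc80=0.2,
                        min_leaf_psi=-1.0, frac_days_below_p50gs=0.0,
                        mean_transpiration=300.0, hsm=1.0,
                        annual_gpp=2000.0, annual_et=800.0)


def _exact_mannwhitney_p(a, b):
    """Two-sided p by full enumeration of group assignments (no ties)."""
    pooled = np.concatenate([a, b])
    n = len(a)

    def u_stat(idx):
        sel = np.zeros(len(pooled), dtype=bool)
        sel[list(idx)] = True
        aa, bb = pooled[sel], pooled[~sel]
        return sum(1.0 for x in aa for y in bb if x > y)

    mu = len(a) * len(b) / 2.0
    u_obs = u_stat(range(n))
    devs = [abs(u_stat(c) - mu)
            for c in itertools.combinations(range(len(pooled)), n)]
    return float(np.mean([d >= abs(u_obs - mu) - 1e-12 for d in devs]))


class TestGroupComparison:
    def test_identical_groups_adjusted_p_one(self):
        with pytest.warns(UserWarning, match="tied"):
            _, _, adj = group_comparison([1.0, 1.0], [1.0, 1.0], m_tests=2)
        assert adj == 1.0

    def test_fully_separated_groups_exact_p(self):
        a = np.arange(1, 11)
        b = np.arange(11, 21)
        u, raw, _ = group_comparison(a, b)
        assert raw == pytest.approx(2.0 / math.comb(20, 10), rel=1e-9)

    def test_bonferroni_cap(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 12), rng.normal(0.1, 1, 12)
        _, raw, adj = group_comparison(a, b, m_tests=5)
        assert adj == min(1.0, 5 * raw)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_exact_enumeration_small_groups(self, seed):
        rng = np.random.default_rng(seed)
        sizes = rng.integers(3, 9, size=2)
        pooled = rng.permutation(np.arange(1.0, 1.0 + sizes.sum()))
        a, b = pooled[:sizes[0]], pooled[sizes[0]:]
        _, raw, _ = group_comparison(a, b)
        assert raw == pytest.approx(_exact_mannwhitney_p(a, b), rel=1e-9)


class TestTraitRegressions:
    def test_perfect_linear_trait(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame({"kmax_plant": rng.uniform(1, 16, 54),
                              "srl": rng.uniform(5, 60, 54)})
        y = 0.03 * table["kmax_plant"].to_numpy()
        filtered, full = trait_regressions(table, y)
        row = full[full["trait"] == "kmax_plant"].iloc[0]
        assert row["r2"] == pytest.approx(1.0)
        assert "kmax_plant" in set(filtered["trait"])

    def test_null_noise_excluded_in_most_replicates(self):
        rng = np.random.default_rng(7)
        excluded = 0
        x = rng.uniform(0, 1, 54)
        table = pd.DataFrame({"vcmax25": x})
        for _ in range(100):
            y = rng.normal(0, 1, 54)
            filtered, _ = trait_regressions(table, y)
            excluded += int(len(filtered) == 0)
        assert excluded >= 90

    def test_r2_filter_applies_even_when_significant(self):
        rng = np.random.default_rng(3)
        n = 20000
        x = rng.uniform(0, 1, n)
        y = 0.25 * x + rng.normal(0, 1.0, n)  # p tiny, R2 ~ 0.005
        table = pd.DataFrame({"sla": x})
        filtered, full = trait_regressions(table, y)
        row = full.iloc[0]
        assert row["p"] < 0.05 and row["r2"] <= 0.01
        assert len(filtered) == 0

    def test_zero_variance_trait_skipped(self):
        table = pd.DataFrame({"g1": np.full(10, 8.0),
                              "g0": np.linspace(0.01, 0.02, 10)})
        with pytest.warns(UserWarning, match="zero variance"):
            _, full = trait_regressions(table, np.arange(10.0))
        assert set(full["trait"]) == {"g0"}


def _balanced_two_factor(n_a=100, n_b=100, seed=0):
    """y = a_i + b_j + eps with empirical Var(a):Var(b):Var(eps) = 4:1:0.05."""
    rng = np.random.default_rng(seed)

    def scaled(v, var):
        v = v - v.mean()
        return v * math.sqrt(var) / v.std()

    a = scaled(rng.normal(size=n_a), 4.0)
    b = scaled(rng.normal(size=n_b), 1.0)
    eps = scaled(rng.normal(size=n_a * n_b), 0.05)
    ii, jj = np.meshgrid(range(n_a), range(n_b), indexing="ij")
    y = a[ii.ravel()] + b[jj.ravel()] + eps
    return pd.DataFrame({"fa": ii.ravel(), "fb": jj.ravel(), "y": y})


class TestVarianceDecomposition:
    def test_single_varying_factor_takes_all(self):
        df = pd.DataFrame({"fa": [0, 0, 1, 1], "fb": [0, 0, 0, 0],
                           "y": [1.0, 1.0, 3.0, 3.0]})
        with pytest.warns(UserWarning):
            shares = variance_decomposition(df, "y", factors=["fa", "fb"])
        assert shares["fa"] == pytest.approx(100.0)
        assert shares["fb"] == 0.0
        assert shares["residual"] == pytest.approx(0.0, abs=1e-9)

    def test_recovers_known_generator_shares(self):
        df = _balanced_two_factor()
        shares = variance_decomposition(df, "y", factors=["fa", "fb"])
        assert shares["fa"] == pytest.approx(100 * 4.0 / 5.05, abs=2.0)
        assert shares["fb"] == pytest.approx(100 * 1.0 / 5.05, abs=2.0)
        assert shares["residual"] == pytest.approx(100 * 0.05 / 5.05, abs=2.0)

    def test_shares_sum_to_hundred(self):
        df = _balanced_two_factor(seed=5)
        shares = variance_decomposition(df, "y", factors=["fa", "fb"])
        assert sum(shares.values()) == pytest.approx(100.0, abs=1e-10)

    def test_affine_invariance(self):
        df = _balanced_two_factor(seed=6)
        s1 = variance_decomposition(df, "y", factors=["fa", "fb"])
        df2 = df.assign(y=3.0 * df["y"] - 17.0)
        s2 = variance_decomposition(df2, "y", factors=["fa", "fb"])
        for k in s1:
            assert s1[k] == pytest.approx(s2[k], abs=1e-9)


def _results_table():
    rows = []
    for aid, base_gpp in [(1, 1000.0), (2, 2000.0)]:
        rows.append({"assemblage_id": aid, "climate_model": "observed",
                     "scenario": "contemporary", "co2_mode": "contemporary",
                     "annual_gpp": base_gpp, "annual_et": 800.0,
                     "frac_days_plc60": 0.0})
        for model, factor in [("m1", 1.267), ("m2", 0.9)]:
            rows.append({"assemblage_id": aid, "climate_model": model,
                         "scenario": "SSP2-45", "co2_mode": "anticipated",
                         "annual_gpp": base_gpp * factor,
                         "annual_et": 800.0 * 1.1,
                         "frac_days_plc60": 0.05 * aid})
    return pd.DataFrame(rows)


class TestRelativeChange:
    def test_identity_is_zero_percent(self):
        df = _results_table()
        future = df["scenario"] != "contemporary"
        df.loc[future, "annual_gpp"] = \
            df.loc[future, "assemblage_id"].map({1: 1000.0, 2: 2000.0})
        df.loc[future, "annual_et"] = 800.0
        per_model = relative_change_table(df)
        np.testing.assert_allclose(per_model["annual_gpp_change_pct"], 0.0,
                                   atol=1e-12)
        np.testing.assert_allclose(per_model["annual_et_change_pct"], 0.0,
                                   atol=1e-12)

    def test_percent_change_arithmetic(self):
        per_model = relative_change_table(_results_table())
        m1 = per_model[per_model["climate_model"] == "m1"].iloc[0]
        assert m1["annual_gpp_change_pct"] == pytest.approx(26.7, abs=1e-9)

    def test_across_model_range_is_order_statistics(self):
        per_model = relative_change_table(_results_table())
        rng_tbl = across_model_range(per_model, "annual_gpp_change_pct")
        row = rng_tbl.iloc[0]
        assert row["min"] == pytest.approx(-10.0, abs=1e-9)
        assert row["max"] == pytest.approx(26.7, abs=1e-9)

    def test_missing_baseline_is_an_error(self):
        df = _results_table()
        df = df[~((df["assemblage_id"] == 2)
                  & (df["scenario"] == "contemporary"))]
        with pytest.raises(ValueError, match="baseline"):
            relative_change_table(df)


def test_failure_group_split():
    df = _results_table()
    failed, safe = failure_group_split(df)
    assert failed == [1, 2] and safe == []
    df.loc[df["assemblage_id"] == 1, "frac_days_plc60"] = 0.0
    failed, safe = failure_group_split(df)
    assert failed == [2] and safe == [1]
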