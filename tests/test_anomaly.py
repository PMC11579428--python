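"""Weekly delta-change anomalies: computation, application, round trip."""
import numpy as np
import pandas as pd
import pytest

from hydrostand.anomaly import (AnomalySet, N_WEEKS, anomaly_sets_from_csv,
                                anomaly_sets_to_csv, apply_anomaly,
                                compute_weekly_anomaly, week_of_year)
from hydrostand.forcing import ForcingSeries
from hydrostand.synthetic import SiteClimateSpec, generate_forcing


@pytest.fixture(scope="module")
def contemporary():
    """Two years with a drizzle floor so every week has nonzero mean rain."""
    f = generate_forcing(SiteClimateSpec(), 2, seed=21)
    df = f.df.copy()
    df["precip_mm"] = df["precip_mm"] + 0.02
    return ForcingSeries(df)


def _unit_anomaly(co2=603.0, scenario="SSP2-45"):
    return AnomalySet("m", scenario, co2, np.ones(N_WEEKS), np.ones(N_WEEKS))


class TestWeekOfYear:
    def test_remainder_bin(self):
        t = pd.to_datetime(["2003-01-01", "2003-01-07", "2003-01-08",
                            "2003-12-31", "2004-12-31"])
        assert list(week_of_year(t)) == [1, 1, 2, 53, 53]

    def test_same_binning_both_directions(self, contemporary):
        wk = week_of_year(contemporary.df["timestamp"])
        assert wk.min() == 1 and wk.max() == N_WEEKS


class TestComputeAnomaly:
    def test_identical_series_unity(self, contemporary):
        a = compute_weekly_anomaly(contemporary, contemporary)
        np.testing.assert_allclose(a.precip_factors, 1.0, atol=1e-12)
        np.testing.assert_allclose(a.temp_values, 1.0, atol=1e-12)

    def test_uniform_precip_scaling(self, contemporary):
        df = contemporary.df.copy()
        df["precip_mm"] = 1.1 * df["precip_mm"]
        a = compute_weekly_anomaly(contemporary, ForcingSeries(df))
        np.testing.assert_allclose(a.precip_factors, 1.1, rtol=1e-12)

    def test_additive_temperature_offset(self, contemporary):
        df = contemporary.df.copy()
        df["tair_C"] = df["tair_C"] + 2.0
        a = compute_weekly_anomaly(contemporary, ForcingSeries(df),
                                   temp_mode="additive")
        np.testing.assert_allclose(a.temp_values, 2.0, atol=1e-10)

    def test_zero_precip_week_warns_factor_one(self):
        times = pd.date_range("2003-01-01", periods=365 * 24, freq="h")
        base = pd.DataFrame({"timestamp": times, "tair_C": 26.0,
                             "precip_mm": 0.0, "swdown_Wm2": 100.0,
                             "rh_pct": 80.0, "co2_ppm": 367.0})
        fut = base.copy()
        fut["precip_mm"] = 1.0
        with pytest.warns(UserWarning, match="zero historical"):
            a = compute_weekly_anomaly(ForcingSeries(base), ForcingSeries(fut))
        assert np.all(a.precip_factors == 1.0)


class TestApplyAnomaly:
    def test_identity_is_noop(self, contemporary):
        out = apply_anomaly(contemporary, _unit_anomaly(), "contemporary")
        pd.testing.assert_frame_equal(out.df, contemporary.df)

    def test_flat_percent_anomaly_scales_annual_totals(self, contemporary):
        # a flat -10.63% precipitation anomaly applied to every week
        a = AnomalySet("flat", "SSP2-45", 603.0, np.ones(N_WEEKS),
                       np.full(N_WEEKS, 0.8937))
        out = apply_anomaly(contemporary, a, "contemporary")
        for year in out.whole_years():
            sel_o = contemporary.df["timestamp"].dt.year == year
            before = contemporary.df.loc[sel_o, "precip_mm"].sum()
            after = out.df.loc[sel_o, "precip_mm"].sum()
            assert after == pytest.approx(0.8937 * before, rel=1e-12)

    def test_anticipated_co2_level(self, contemporary):
        a = _unit_anomaly(co2=1059.0, scenario="SSP5-85")
        out = apply_anomaly(contemporary, a, "anticipated")
        assert (out.df["co2_ppm"] == 1059.0).all()

    def test_contemporary_co2_preserved(self, contemporary):
        a = _unit_anomaly(co2=1059.0, scenario="SSP5-85")
        out = apply_anomaly(contemporary, a, "contemporary")
        np.testing.assert_array_equal(out.df["co2_ppm"].to_numpy(),
                                      contemporary.df["co2_ppm"].to_numpy())

    def test_humidity_preserved_so_vpd_rises(self, contemporary):
        a = AnomalySet("w", "SSP5-85", 1059.0, np.full(N_WEEKS, 1.10),
                       np.ones(N_WEEKS))
        out = apply_anomaly(contemporary, a, "anticipated")
        np.testing.assert_array_equal(out.df["rh_pct"].to_numpy(),
                                      contemporary.df["rh_pct"].to_numpy())
        assert out.vpd_kpa().mean() > contemporary.vpd_kpa().mean()


class TestRoundTrip:
    def test_factors_recovered_to_1e10(self, contemporary):
        rng = np.random.default_rng(3)
        a = AnomalySet("rt", "SSP2-45", 603.0,
                       1.0 + 0.1 * rng.random(N_WEEKS),
                       0.5 + rng.random(N_WEEKS))
        fut = apply_anomaly(contemporary, a, "anticipated")
        back = compute_weekly_anomaly(contemporary, fut)
        np.testing.assert_allclose(back.precip_factors, a.precip_factors,
                                   atol=1e-10)
        np.testing.assert_allclose(back.temp_values, a.temp_values, atol=1e-10)

    def test_record_count_and_nonnegativity_preserved(self, contemporary):
        a = AnomalySet("z", "SSP2-45", 603.0, np.ones(N_WEEKS),
                       np.zeros(N_WEEKS))
        out = apply_anomaly(contemporary, a, "anticipated")
        assert len(out) == len(contemporary)
        assert (out.df["precip_mm"] >= 0).all()


def test_csv_round_trip(tmp_path):
    rng = np.random.default_rng(5)
    sets = [AnomalySet(f"m{i}", "SSP5-85", 1059.0,
                       1.0 + 0.05 * rng.random(N_WEEKS),
                       0.8 + 0.4 * rng.random(N_WEEKS)) for i in range(3)]
    anomaly_sets_to_csv(sets, tmp_path / "a.csv")
    back = anomaly_sets_from_csv(tmp_path / "a.csv")
    assert [b.model_name for b in back] == ["m0", "m1", "m2"]
    np.testing.assert_allclose(back[1].precip_factors, sets[1].precip_factors)
    assert back[0].co2_ppm == 1059.0
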