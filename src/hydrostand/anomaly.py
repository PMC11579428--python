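"""Delta-change climate projection via weekly anomalies.

The weekly anomaly between a paired historical and future series is the
ratio (or offset, for temperature in additive mode) of the week-of-year means
across years. Applying an anomaly set rescales a contemporary forcing series
week by week and pins CO2 at the scenario level; relative humidity is carried
unchanged, so vapor pressure deficit rises with warming.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .forcing import ForcingSeries, vpd_from_t_rh  # noqa: F401  (re-export)

N_WEEKS = 53
SCENARIOS = ("SSP2-45", "SSP5-85")
SCENARIO_CO2 = {"SSP2-45": 603.0, "SSP5-85": 1059.0}
CONTEMPORARY_CO2 = 367.0


def week_of_year(timestamps) -> np.ndarray:
    """Week-of-year bins 1..53: seven-day blocks of the day-of-year, with
    days 365/366 falling into the remainder bin 53.

    The same binning is used when computing and when applying anomalies.
    """
    doy = pd.DatetimeIndex(timestamps).dayofyear.to_numpy()
    return np.minimum((doy - 1) // 7 + 1, N_WEEKS)


@dataclasses.dataclass
class AnomalySet:
    """Per-week-of-year temperature and precipitation anomalies plus scenario
    metadata. ``temp_mode`` is "relative" (multiplicative factors) or
    "additive" (offsets in degrees C)."""

    model_name: str
    scenario: str
    co2_ppm: float
    temp_values: np.ndarray     # (53,) factors or offsets
    precip_factors: np.ndarray  # (53,) multiplicative, >= 0
    temp_mode: str = "relative"

    def __post_init__(self):
        self.temp_values = np.asarray(self.temp_values, dtype=float)
        self.precip_factors = np.asarray(self.precip_factors, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.temp_values.shape != (N_WEEKS,):
            raise ValueError(f"temp_values must have {N_WEEKS} weeks")
        if self.precip_factors.shape != (N_WEEKS,):
            raise ValueError(f"precip_factors must have {N_WEEKS} weeks")
        if np.any(self.precip_factors < 0):
            raise ValueError("precip factors must be >= 0")
        if self.co2_ppm <= 0:
            raise ValueError("co2_ppm must be positive")
        if self.temp_mode not in ("relative", "additive"):
            raise ValueError("temp_mode must be 'relative' or 'additive'")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "model": self.model_name,
            "scenario": self.scenario,
            "co2_ppm": self.co2_ppm,
            "temp_mode": self.temp_mode,
            "week": np.arange(1, N_WEEKS + 1),
            "temp_factor": self.temp_values,
            "precip_factor": self.precip_factors,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AnomalySet":
        df = df.sort_values("week")
        return cls(model_name=str(df["model"].iloc[0]),
                   scenario=str(df["scenario"].iloc[0]),
                   co2_ppm=float(df["co2_ppm"].iloc[0]),
                   temp_values=df["temp_factor"].to_numpy(),
                   precip_factors=df["precip_factor"].to_numpy(),
                   temp_mode=str(df.get("temp_mode", pd.Series(["relative"])).iloc[0]))

    def annual_summary(self, weekly_precip_weights: np.ndarray | None = None) -> dict:
        """Annual percent anomalies for quick inspection (Table-style summary).

        Precipitation weeks are weighted by ``weekly_precip_weights`` (uniform
        when omitted) because a weekly factor matters in proportion to how
        much rain that week carries.
        """
        w = (np.ones(N_WEEKS) if weekly_precip_weights is None
             else np.asarray(weekly_precip_weights, dtype=float))
        w = w / w.sum()
        precip_pct = (float(np.sum(self.precip_factors * w)) - 1.0) * 100.0
        if self.temp_mode == "relative":
            temp_pct = (float(np.mean(self.temp_values)) - 1.0) * 100.0
        else:
            temp_pct = float(np.mean(self.temp_values))  # degrees C offset
        return {"model": self.model_name, "scenario": self.scenario,
                "co2_ppm": self.co2_ppm, "temp_anomaly_pct": temp_pct,
                "precip_anomaly_pct": precip_pct}


def anomaly_sets_to_csv(sets, path) -> None:
    pd.concat([a.to_frame() for a in sets], ignore_index=True).to_csv(path, index=False)


def anomaly_sets_from_csv(path) -> list:
    df = pd.read_csv(path)
    out = []
    for (_model, _scen), grp in df.groupby(["model", "scenario"], sort=False):
        out.append(AnomalySet.from_frame(grp))
    return out


def compute_weekly_anomaly(historical: ForcingSeries, future: ForcingSeries,
                           model_name: str = "", scenario: str = "",
                           co2_ppm: float = CONTEMPORARY_CO2,
                           temp_mode: str = "relative") -> AnomalySet:
    """Weekly anomaly between paired historical and future forcing.

    For each week-of-year, factor = mean(future)/mean(historical) over all
    years; precipitation weeks with a zero historical mean get factor 1 with
    a warning. Temperature is handled per ``temp_mode``.
    """
    out_t = np.empty(N_WEEKS)
    out_p = np.empty(N_WEEKS)
    frames = []
    for f in (historical, future):
        df = f.df
        wk = week_of_year(df["timestamp"])
        g = df.groupby(wk)
        frames.append((g["tair_C"].mean(), g["precip_mm"].mean()))
    (t_hist, p_hist), (t_fut, p_fut) = frames
    for series in (t_hist, p_hist, t_fut, p_fut):
        present = set(series.index)
        missing = [w for w in range(1, N_WEEKS + 1) if w not in present]
        if missing:
            raise ValueError(f"weeks {missing} missing from a source series")
    for w in range(1, N_WEEKS + 1):
        if p_hist[w] == 0.0:
            if p_fut[w] != 0.0:
                warnings.warn(f"week {w}: zero historical precipitation; "
                              "factor set to 1", stacklevel=2)
            out_p[w - 1] = 1.0
        else:
            out_p[w - 1] = p_fut[w] / p_hist[w]
        if temp_mode == "relative":
            out_t[w - 1] = t_fut[w] / t_hist[w]
        else:
            out_t[w - 1] = t_fut[w] - t_hist[w]
    return AnomalySet(model_name=model_name, scenario=scenario, co2_ppm=co2_ppm,
                      temp_values=out_t, precip_factors=np.maximum(out_p, 0.0),
                      temp_mode=temp_mode)


def apply_anomaly(forcing: ForcingSeries, anomaly: AnomalySet,
                  co2_mode: str = "anticipated") -> ForcingSeries:
    """Apply a weekly anomaly set to contemporary forcing.

    Precipitation is multiplied by its week-of-year factor, temperature by its
    factor (or shifted by its offset in additive mode). CO2 is set to the
    scenario level when ``co2_mode`` is "anticipated" and left untouched when
    "contemporary". Relative humidity is preserved.
    """
    if co2_mode not in ("anticipated", "contemporary"):
        raise ValueError("co2_mode must be 'anticipated' or 'contemporary'")
    df = forcing.df.copy()
    wk = week_of_year(df["timestamp"]) - 1
    df["precip_mm"] = df["precip_mm"].to_numpy() * anomaly.precip_factors[wk]
    if anomaly.temp_mode == "relative":
        df["tair_C"] = df["tair_C"].to_numpy() * anomaly.temp_values[wk]
    else:
        df["tair_C"] = df["tair_C"].to_numpy() + anomaly.temp_values[wk]
    if co2_mode == "anticipated":
        df["co2_ppm"] = anomaly.co2_ppm
    return ForcingSeries(df)
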