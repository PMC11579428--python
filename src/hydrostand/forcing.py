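"""Meteorological forcing series: validation, derived variables, CSV/NetCDF I/O.

The canonical layout is an hourly table with columns
``timestamp, tair_C, precip_mm, swdown_Wm2, rh_pct, co2_ppm`` (ISO-8601
timestamps). The NetCDF layout mirrors it with one time dimension and named
variables; both readers produce bit-equivalent values.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

COLUMNS = ["timestamp", "tair_C", "precip_mm", "swdown_Wm2", "rh_pct", "co2_ppm"]


def vpd_from_t_rh(tair_c, rh_pct):
    """Vapor pressure deficit (kPa) from air temperature (C) and RH (%).

    Tetens saturation vapor pressure: es = 0.6108 exp(17.27 T / (T + 237.3)).
    """
    tair_c = np.asarray(tair_c, dtype=float)
    rh_pct = np.asarray(rh_pct, dtype=float)
    if np.any(rh_pct < 0) or np.any(rh_pct > 100):
        raise ValueError("rh_pct must be within [0, 100]")
    es = 0.6108 * np.exp(17.27 * tair_c / (tair_c + 237.3))
    vpd = es * (1.0 - rh_pct / 100.0)
    return vpd if vpd.ndim else float(vpd)


class ForcingSeries:
    """Gap-free hourly meteorological driver series with CO2."""

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"forcing table missing columns: {missing}")
        df = df[COLUMNS].copy()
        df["timestamp"] = pd.to_datetime(df["timestamp"])
        self.df = df.reset_index(drop=True)
        if validate:
            self.validate()

    def validate(self) -> None:
        t = self.df["timestamp"]
        dt = t.diff().dropna()
        if len(t) < 2:
            raise ValueError("forcing series must contain at least two steps")
        if not (dt > pd.Timedelta(0)).all():
            raise ValueError("timestamps must be strictly increasing")
        if dt.nunique() != 1:
            raise ValueError("forcing series has gaps or irregular steps")
        if (self.df["precip_mm"] < 0).any():
            raise ValueError("negative precipitation")
        if (self.df["swdown_Wm2"] < 0).any():
            raise ValueError("negative shortwave radiation")
        if ((self.df["rh_pct"] < 0) | (self.df["rh_pct"] > 100)).any():
            raise ValueError("relative humidity outside [0, 100]")
        if (self.df["co2_ppm"] <= 0).any():
            raise ValueError("non-positive CO2")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def step(self) -> pd.Timedelta:
        return self.df["timestamp"].iloc[1] - self.df["timestamp"].iloc[0]

    def vpd_kpa(self) -> np.ndarray:
        return vpd_from_t_rh(self.df["tair_C"].to_numpy(),
                             self.df["rh_pct"].to_numpy())

    def whole_years(self) -> list[int]:
        """Calendar years fully covered by the series."""
        t = self.df["timestamp"]
        out = []
        for year, grp in t.groupby(t.dt.year):
            first, last = grp.iloc[0], grp.iloc[-1]
            if (first <= pd.Timestamp(year=year, month=1, day=1, hour=0)
                    and last >= pd.Timestamp(year=year, month=12, day=31, hour=23)):
                out.append(int(year))
        return out

    def annual_aggregates(self) -> pd.DataFrame:
        """Per whole calendar year: mean temperature and total precipitation."""
        years = self.whole_years()
        t = self.df["timestamp"].dt.year
        rows = []
        for y in years:
            sel = self.df[t == y]
            rows.append({"year": y,
                         "tair_mean_C": sel["tair_C"].mean(),
                         "precip_total_mm": sel["precip_mm"].sum()})
        return pd.DataFrame(rows)

    def copy(self) -> "ForcingSeries":
        return ForcingSeries(self.df.copy(), validate=False)

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path) -> None:
        df = self.df.copy()
        df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
        # %.17g round-trips float64 exactly, keeping both readers bit-equal
        df.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "ForcingSeries":
        return cls(pd.read_csv(path, float_precision="round_trip"))

    def to_netcdf(self, path) -> None:
        ds = xr.Dataset(
            {c: ("time", self.df[c].to_numpy(dtype=float)) for c in COLUMNS[1:]},
            coords={"time": self.df["timestamp"].to_numpy()})
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "ForcingSeries":
        with xr.open_dataset(path, engine="scipy") as ds:
            df = pd.DataFrame({"timestamp": pd.to_datetime(ds["time"].values)})
            for c in COLUMNS[1:]:
                df[c] = np.asarray(ds[c].values, dtype=float)
        return cls(df)
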