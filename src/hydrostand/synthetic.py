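"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators: (1) a stochastic hourly weather series for a wet tropical
site (seasonal and diurnal temperature cycles, Markov-chain rain occurrence
with gamma wet-day amounts, wetter-season humidity and cloudiness); (2)
log-normally perturbed monthly observations derived from a known-truth
simulation; (3) an ensemble of weekly anomaly sets spanning configured
annual temperature/precipitation anomaly ranges, with precipitation change
concentrated early and late in the year.

Everything is reproducible from an integer seed and passes the consuming
modules' validity checks, so the full pipeline is testable offline.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .anomaly import (CONTEMPORARY_CO2, N_WEEKS, SCENARIO_CO2, SCENARIOS,
                      AnomalySet)
from .forcing import ForcingSeries
from .simulate import SimulationOutput

DRY_MONTHS_DEFAULT = frozenset({12, 1, 2, 3, 4, 5})


@dataclasses.dataclass
class SiteClimateSpec:
    """Climatological targets for the weather generator (wet tropical site)."""

    annual_mean_temp: float = 26.3       # degrees C
    annual_precip: float = 2656.0        # mm
    dry_season_months: frozenset = DRY_MONTHS_DEFAULT
    dry_season_precip: float = 140.0     # mm over the dry season
    diurnal_temp_range: float = 8.0      # degrees C
    seasonal_temp_amplitude: float = 1.0 # degrees C
    rh_wet: float = 90.0                 # %
    rh_dry: float = 75.0                 # %
    co2_ppm: float = CONTEMPORARY_CO2
    sw_peak: float = 900.0               # W m-2 clear-sky midday
    wet_day_prob_dry: float = 0.20       # wet-day probability, dry season
    wet_day_prob_wet: float = 0.85       # wet-day probability, wet season
    rain_persistence: float = 0.25       # added wet->wet persistence
    gamma_shape: float = 1.0             # wet-day amount distribution

    def __post_init__(self):
        if not self.dry_season_precip < self.annual_precip:
            raise ValueError("dry_season_precip must be below annual_precip")


@dataclasses.dataclass
class EnsembleClimateSpec:
    """Spread of annual anomalies across a synthetic climate-model ensemble.

    Default ranges mimic a CMIP6-style ensemble for a wet tropical site:
    moderate-scenario warming with mostly drying, high-scenario warming with
    a wide precipitation spread. CO2 levels default to 603 ppm (moderate) and
    1059 ppm (high) against a contemporary 367 ppm.
    """

    n_models: int = 16
    temp_pct_range: dict = dataclasses.field(default_factory=lambda: {
        "SSP2-45": (3.5, 11.7), "SSP5-85": (8.0, 21.5)})
    precip_pct_range: dict = dataclasses.field(default_factory=lambda: {
        "SSP2-45": (-28.3, -2.5), "SSP5-85": (-61.4, 67.7)})
    co2_ppm: dict = dataclasses.field(default_factory=lambda: dict(SCENARIO_CO2))
    reduction_weeks: tuple = ((1, 15), (40, 50))  # where precip change concentrates

    def __post_init__(self):
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")


def _season_weights(spec: SiteClimateSpec, months: np.ndarray) -> np.ndarray:
    return np.isin(months, list(spec.dry_season_months))


def generate_forcing(spec: SiteClimateSpec, years: int, seed: int,
                     start_year: int = 2003) -> ForcingSeries:
    """Hourly synthetic forcing matching the site climatology in expectation."""
    if years < 1:
        raise ValueError("years must be >= 1")
    rng = np.random.default_rng(seed)
    start = pd.Timestamp(year=start_year, month=1, day=1)
    n_days = (pd.Timestamp(year=start_year + years, month=1, day=1) - start).days
    times = pd.date_range(start, periods=n_days * 24, freq="h")
    n = len(times)
    months = times.month.to_numpy()
    doy = times.dayofyear.to_numpy()
    hour = times.hour.to_numpy()
    dry = _season_weights(spec, months)

    # temperature: seasonal sinusoid (warm late dry season) + diurnal harmonic
    seasonal = spec.seasonal_temp_amplitude * np.cos(2 * np.pi * (doy - 105) / 365.0)
    diurnal = -0.5 * spec.diurnal_temp_range * np.cos(2 * np.pi * (hour - 14) / 24.0)
    ar_noise = np.empty(n)
    eps = rng.normal(0.0, 0.4, size=n)
    ar_noise[0] = eps[0]
    phi = 0.95
    for i in range(1, n):
        ar_noise[i] = phi * ar_noise[i - 1] + eps[i]
    tair = spec.annual_mean_temp + seasonal + diurnal + ar_noise

    # precipitation: daily two-state Markov occurrence, gamma amounts,
    # amounts spread over a few afternoon hours
    n_days = n // 24
    day_month = months[::24]
    day_dry = dry[::24]
    n_dry_days = int(day_dry[:365].sum())
    n_wet_days = 365 - n_dry_days
    p_wet = np.where(day_dry, spec.wet_day_prob_dry, spec.wet_day_prob_wet)
    mean_amt_dry = spec.dry_season_precip / max(n_dry_days * spec.wet_day_prob_dry, 1e-9)
    wet_total = spec.annual_precip - spec.dry_season_precip
    mean_amt_wet = wet_total / max(n_wet_days * spec.wet_day_prob_wet, 1e-9)
    precip = np.zeros(n)
    wet_prev = False
    for d in range(n_days):
        # two-state chain with stationary wet probability p_wet:
        # P(wet|wet) = p + r(1-p), P(wet|dry) = p(1-r)
        if wet_prev:
            p_eff = p_wet[d] + spec.rain_persistence * (1 - p_wet[d])
        else:
            p_eff = p_wet[d] * (1 - spec.rain_persistence)
        wet = rng.random() < p_eff
        if wet:
            mean_amt = mean_amt_dry if day_dry[d] else mean_amt_wet
            amount = rng.gamma(spec.gamma_shape, mean_amt / spec.gamma_shape)
            n_h = rng.integers(1, 7)
            start_h = rng.integers(11, 22 - n_h)
            weights = rng.dirichlet(np.ones(n_h))
            precip[24 * d + start_h: 24 * d + start_h + n_h] = amount * weights
        wet_prev = wet

    # shortwave: half-sine day course, cloudier in the wet season and on rain days
    day_shape = np.maximum(np.sin(np.pi * (hour - 6) / 12.0), 0.0)
    cloud = np.where(dry, 0.75, 0.55)
    rain_day = np.repeat(precip.reshape(-1, 24).sum(axis=1) > 0, 24)
    cloud = cloud * np.where(rain_day, 0.75, 1.0)
    sw = spec.sw_peak * day_shape * cloud

    # relative humidity: seasonal base, higher at night, saturated-ish in rain
    rh_base = np.where(dry, spec.rh_dry, spec.rh_wet)
    rh = rh_base + 6.0 * np.cos(2 * np.pi * (hour - 4) / 24.0) \
        + rng.normal(0.0, 2.0, size=n)
    rh = np.where(precip > 0, np.maximum(rh, 95.0), rh)
    rh = np.clip(rh, 20.0, 100.0)

    df = pd.DataFrame({
        "timestamp": times,
        "tair_C": tair,
        "precip_mm": precip,
        "swdown_Wm2": sw,
        "rh_pct": rh,
        "co2_ppm": spec.co2_ppm,
    })
    return ForcingSeries(df)


def generate_observations(truth_output: SimulationOutput, sigma_log: dict,
                          seed: int):
    """Monthly observations from a known-truth run with log-normal noise.

    ``sigma_log`` maps each variable (et, gpp, swc, runoff) to the standard
    deviation of its natural log. obs = truth * exp(eps), eps ~ N(0, sigma^2),
    independent across months and variables. Zero truth months are floored at
    a small epsilon and flagged in the returned frame.
    """
    from .calibration import ObservationSet

    rng = np.random.default_rng(seed)
    monthly = truth_output.monthly_observables()
    rows = []
    for var in ("et", "gpp", "swc", "runoff"):
        sig = float(sigma_log[var])
        if sig < 0:
            raise ValueError("sigma_log must be >= 0")
        truth = monthly[var].to_numpy(dtype=float)
        floored = truth <= 0
        truth = np.where(floored, 1e-6, truth)
        obs = truth * np.exp(rng.normal(0.0, sig, size=len(truth))) if sig > 0 else truth
        for month, value, flag in zip(monthly.index, obs, floored):
            rows.append({"month": str(month), "variable": var, "value": value,
                         "sigma_log": max(sig, 1e-6), "floored": bool(flag)})
    return ObservationSet(pd.DataFrame(rows))


def _raised_cosine_weights(windows) -> np.ndarray:
    w = np.zeros(N_WEEKS)
    for lo, hi in windows:
        span = hi - lo
        for k in range(lo, hi + 1):
            w[k - 1] = max(w[k - 1],
                           0.5 * (1 - np.cos(2 * np.pi * (k - lo) / max(span, 1))))
    return w


def generate_future_ensemble(spec: EnsembleClimateSpec, seed: int,
                             weekly_precip_weights: np.ndarray | None = None):
    """One anomaly set per (model, scenario) spanning the configured ranges.

    Annual anomalies are stratified across models (evenly spaced quantiles in
    the configured range, shuffled) so a small ensemble still spans the
    spread. Weekly precipitation shaping concentrates the change in the
    configured windows via a raised-cosine weight; renormalization against
    the site's climatological weekly precipitation profile makes the annual
    aggregate anomaly exact.
    """
    rng = np.random.default_rng(seed)
    weights = _raised_cosine_weights(spec.reduction_weeks)
    if weekly_precip_weights is None:
        weekly_precip_weights = climatological_weekly_precip(SiteClimateSpec())
    m_w = np.asarray(weekly_precip_weights, dtype=float)
    m_w = m_w / m_w.sum()
    out = []
    for scenario in SCENARIOS:
        t_lo, t_hi = spec.temp_pct_range[scenario]
        p_lo, p_hi = spec.precip_pct_range[scenario]
        q = (np.arange(spec.n_models) + rng.random(spec.n_models)) / spec.n_models
        temps = t_lo + (t_hi - t_lo) * rng.permutation(q)
        precs = p_lo + (p_hi - p_lo) * rng.permutation(q)
        for i in range(spec.n_models):
            a_p = precs[i] / 100.0
            # shape the change, then renormalize so sum(m_w * f) = 1 + a_p
            factors = 1.0 + weights * a_p / max(np.sum(m_w * weights), 1e-12)
            factors = np.maximum(factors, 0.0)
            # clipping at zero can bias the total; iterate the renormalization
            for _ in range(8):
                achieved = np.sum(m_w * factors) - 1.0
                if abs(achieved - a_p) < 1e-12:
                    break
                free = factors > 0
                adj = (a_p - achieved) / max(np.sum(m_w[free] * weights[free]), 1e-12)
                factors = np.where(free, factors + weights * adj, factors)
                factors = np.maximum(factors, 0.0)
            out.append(AnomalySet(
                model_name=f"SYN-{i + 1:02d}",
                scenario=scenario,
                co2_ppm=float(spec.co2_ppm[scenario]),
                temp_values=np.full(N_WEEKS, 1.0 + temps[i] / 100.0),
                precip_factors=factors,
                temp_mode="relative"))
    return out


def climatological_weekly_precip(spec: SiteClimateSpec) -> np.ndarray:
    """Expected precipitation per week-of-year implied by the site spec (mm)."""
    doy_month = pd.date_range("2001-01-01", periods=365, freq="D").month.to_numpy()
    dry = np.isin(doy_month, list(spec.dry_season_months))
    n_dry = int(dry.sum())
    daily = np.where(dry, spec.dry_season_precip / n_dry,
                     (spec.annual_precip - spec.dry_season_precip) / (365 - n_dry))
    week = np.minimum(np.arange(365) // 7 + 1, N_WEEKS)
    return np.bincount(week, weights=daily, minlength=N_WEEKS + 1)[1:]
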