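"""Headline risk metrics and statistics for batches of scenario runs.

Hydraulic-failure exceedance fractions (days above the 60%/80% loss-of-
conductivity thresholds), leaf stress indicators, hydraulic safety margin,
nonparametric group comparisons with Bonferroni correction, per-trait
regressions of failure risk, main-effects variance decomposition, and
relative-change summaries against the contemporary baseline.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import SimulationOutput
from .traits import TraitAssemblage

RESULT_FACTORS = ["assemblage_id", "climate_model", "scenario", "co2_mode"]


@dataclasses.dataclass(frozen=True)
class RiskSummary:
    """Per-(assemblage x scenario) derived metrics."""

    frac_days_plc60: float
    frac_days_plc80: float
    min_leaf_psi: float          # MPa
    frac_days_below_p50gs: float
    mean_transpiration: float    # mm yr-1
    hsm: float                   # MPa, min stem psi minus stem P50
    annual_gpp: float            # g C m-2 yr-1
    annual_et: float             # mm yr-1

    def __post_init__(self):
        for f in ("frac_days_plc60", "frac_days_plc80", "frac_days_below_p50gs"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f} outside [0, 1]: {v}")
        if self.frac_days_plc80 > self.frac_days_plc60 + 1e-12:
            raise ValueError("frac_days_plc80 exceeds frac_days_plc60")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def exceedance_fraction(plc_series, threshold: float) -> float:
    """Fraction of days with PLC strictly above the threshold.

    Strict inequality: a day sitting exactly at the threshold is not an
    exceedance ("> 60% loss").
    """
    plc = np.asarray(plc_series, dtype=float)
    if plc.size == 0:
        raise ValueError("empty PLC series")
    return float(np.count_nonzero(plc > threshold) / plc.size)


def stress_indicators(output: SimulationOutput,
                      assemblage: TraitAssemblage) -> RiskSummary:
    """Summarize one run into the headline risk metrics."""
    df = output.df
    psi_leaf = df["psi_leaf_min"].to_numpy(dtype=float)
    annual = output.annual_totals()
    return RiskSummary(
        frac_days_plc60=exceedance_fraction(df["plc_stem"], 0.60),
        frac_days_plc80=exceedance_fraction(df["plc_stem"], 0.80),
        min_leaf_psi=float(psi_leaf.min()),
        frac_days_below_p50gs=float(np.mean(psi_leaf < assemblage.p50_gs)),
        mean_transpiration=float(annual["transpiration"].mean()),
        hsm=float(df["psi_stem_min"].min() - assemblage.p50_stem),
        annual_gpp=float(annual["gpp"].mean()),
        annual_et=float(annual["et"].mean()),
    )


def group_comparison(group_a, group_b, m_tests: int = 1):
    """Two-sided Mann-Whitney U with Bonferroni correction.

    Returns (U statistic, raw p, adjusted p); degenerate all-tied data yields
    p = 1 with a warning.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("each group needs at least one value")
    if np.ptp(np.concatenate([a, b])) == 0.0:
        warnings.warn("all values tied; reporting p = 1", stacklevel=2)
        return float(a.size * b.size / 2.0), 1.0, 1.0
    no_ties = len(np.unique(np.concatenate([a, b]))) == a.size + b.size
    method = "exact" if no_ties and max(a.size, b.size) <= 25 else "auto"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    raw = float(res.pvalue)
    return float(res.statistic), raw, min(1.0, m_tests * raw)


def trait_regressions(trait_table: pd.DataFrame, response,
                      p_max: float = 0.05, r2_min: float = 0.01):
    """Univariate least-squares of the response on each trait.

    Returns (filtered, full): the full table has one row per trait with
    slope, r2 and p; the filtered view keeps traits with p < ``p_max`` and
    R^2 > ``r2_min``. Zero-variance traits are skipped with a warning.
    """
    y = np.asarray(response, dtype=float)
    if len(trait_table) != len(y):
        raise ValueError("response length does not match trait table")
    if len(y) < 3:
        raise ValueError("need at least 3 assemblages")
    rows = []
    for name in trait_table.columns:
        x = trait_table[name].to_numpy(dtype=float)
        if np.ptp(x) == 0.0:
            warnings.warn(f"trait '{name}' has zero variance; skipped",
                          stacklevel=2)
            continue
        res = stats.linregress(x, y)
        rows.append({"trait": name, "slope": res.slope,
                     "r2": res.rvalue**2, "p": res.pvalue})
    full = pd.DataFrame(rows)
    filtered = full[(full["p"] < p_max) & (full["r2"] > r2_min)].reset_index(drop=True)
    return filtered, full


def variance_decomposition(results: pd.DataFrame, response: str,
                           factors=None) -> dict:
    """Main-effects sum-of-squares decomposition of a factorial response.

    SS_factor = sum over levels of n_level * (level mean - grand mean)^2;
    fractions are percentages of total SS, with interactions and noise folded
    into the reported residual so all entries sum to 100. Single-level
    factors contribute 0% with a warning; a near-full factorial warns but
    proceeds.
    """
    factors = list(RESULT_FACTORS if factors is None else factors)
    y = results[response].to_numpy(dtype=float)
    grand = y.mean()
    ss_total = float(np.sum((y - grand) ** 2))
    if ss_total == 0.0:
        warnings.warn("response has zero variance", stacklevel=2)
        return {**{f: 0.0 for f in factors}, "residual": 0.0}
    sizes = [results[f].nunique() for f in factors]
    if int(np.prod(sizes)) != len(results):
        warnings.warn("design is not a full factorial; main-effects shares "
                      "may be biased", stacklevel=2)
    out = {}
    for f in factors:
        if results[f].nunique() < 2:
            warnings.warn(f"factor '{f}' has a single level; 0% assigned",
                          stacklevel=2)
            out[f] = 0.0
            continue
        g = results.groupby(f)[response]
        ss = float((g.count() * (g.mean() - grand) ** 2).sum())
        out[f] = 100.0 * ss / ss_total
    out["residual"] = 100.0 - sum(out.values())
    return out


def relative_change_table(results: pd.DataFrame,
                          metrics=("annual_gpp", "annual_et")) -> pd.DataFrame:
    """Percent change vs each assemblage's contemporary run, averaged across
    assemblages per (climate model, scenario, CO2 mode).

    Changes are computed per assemblage and then averaged (not a ratio of
    means). The across-model range per (scenario, co2_mode) gives the
    (min, max) convention for reporting climate-model uncertainty.
    """
    base = results[results["scenario"] == "contemporary"]
    if base.empty:
        raise ValueError("no contemporary baseline rows in results")
    base_idx = base.set_index("assemblage_id")
    future = results[results["scenario"] != "contemporary"].copy()
    missing = set(future["assemblage_id"]) - set(base_idx.index)
    if missing:
        raise ValueError(f"missing contemporary baseline for assemblages "
                         f"{sorted(missing)}")
    for mcol in metrics:
        ref = base_idx.loc[future["assemblage_id"], mcol].to_numpy(dtype=float)
        future[f"{mcol}_change_pct"] = (future[mcol].to_numpy() - ref) / ref * 100.0
    cols = [f"{m}_change_pct" for m in metrics]
    per_model = (future.groupby(["climate_model", "scenario", "co2_mode"])[cols]
                 .mean().reset_index())
    return per_model


def across_model_range(per_model: pd.DataFrame, column: str) -> pd.DataFrame:
    """Min/max/mean of per-climate-model means for each (scenario, co2_mode)."""
    g = per_model.groupby(["scenario", "co2_mode"])[column]
    return g.agg(["mean", "min", "max"]).reset_index()


def failure_group_split(results: pd.DataFrame):
    """Assemblage ids that experienced hydraulic failure in any simulation
    (any run with a positive fraction of days above the 60% loss threshold)
    versus those that never did."""
    by_assemblage = results.groupby("assemblage_id")["frac_days_plc60"].max()
    failed = sorted(by_assemblage[by_assemblage > 0].index)
    safe = sorted(by_assemblage[by_assemblage <= 0].index)
    return failed, safe
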