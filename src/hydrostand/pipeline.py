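"""End-to-end experiment: calibrate -> project -> analyze.

One entry point runs the whole design: generate (or load) contemporary
forcing and observations, calibrate the trait ensemble against them, apply
every climate-model anomaly under each emission scenario and CO2 mode to
the contemporary forcing, simulate the selected assemblages in every design
cell, and summarize the results table into the report (per-model flux
changes, hydraulic-failure exceedance, stress-indicator group comparisons,
per-trait regressions, and the factor variance decomposition).

Stages communicate through serialized files in the output directory and the
whole experiment is reproducible from (config, seed).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anomaly import anomaly_sets_to_csv, apply_anomaly
from .calibration import (ObservationSet, PriorSpec, sample_priors,
                          select_assemblages, viability_filter)
from .config import SimConfig
from .forcing import ForcingSeries
from .risk import (across_model_range, failure_group_split, group_comparison,
                   relative_change_table, stress_indicators,
                   trait_regressions, variance_decomposition)
from .simulate import simulate, simulate_ensemble
from .synthetic import (EnsembleClimateSpec, SiteClimateSpec,
                        generate_forcing, generate_future_ensemble,
                        generate_observations)
from .traits import TRAIT_FIELDS, TraitAssemblage, TraitEnsemble

logger = logging.getLogger(__name__)

#: moderate, field-plausible truth assemblage used when observations are synthetic
DEFAULT_TRUTH = TraitAssemblage(
    p50_stem=-3.0, shape_stem=3.0, p50_root=-2.5, shape_root=2.5,
    p50_gs=-1.8, a_gs=3.0, g0=0.015, g1=8.0, theta_sat_stem=0.5,
    resid_frac_stem=0.25, pi0=-1.5, eps_bulk=12.0, cap_frac=0.03,
    kmax_plant=6.0, taper_exp=0.2, srl=25.0, sla=0.015, vcmax25=55.0)

DEFAULT_SIGMA_LOG = {"et": 0.2, "gpp": 0.2, "swc": 0.1, "runoff": 0.3}


@dataclasses.dataclass
class ExperimentConfig:
    output_dir: str = "experiment_out"
    seed: int = 0
    years: int = 3
    ensemble_size: int = 200
    mcmc_steps: int = 20000
    mcmc_burn_in: int = 10000
    selection_method: str = "mcmc"
    n_climate_models: int = 16
    co2_modes: tuple = ("anticipated", "contemporary")
    sigma_log: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_SIGMA_LOG))
    site: SiteClimateSpec = dataclasses.field(default_factory=SiteClimateSpec)
    climate: EnsembleClimateSpec = dataclasses.field(
        default_factory=EnsembleClimateSpec)
    sim: SimConfig = dataclasses.field(default_factory=SimConfig)
    truth: TraitAssemblage = DEFAULT_TRUTH
    forcing_path: str | None = None      # optional real inputs
    observations_path: str | None = None

    @classmethod
    def smoke(cls, output_dir="experiment_out", seed=0) -> "ExperimentConfig":
        """Small design that completes in minutes on one CPU."""
        cfg = cls(output_dir=output_dir, seed=seed, years=3, ensemble_size=20,
                  mcmc_steps=3000, mcmc_burn_in=500, n_climate_models=2)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["site"]["dry_season_months"] = sorted(self.site.dry_season_months)
        d["climate"]["reduction_weeks"] = [list(w) for w in
                                           self.climate.reduction_weeks]
        d["co2_modes"] = list(self.co2_modes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if isinstance(d.get("site"), dict):
            s = dict(d["site"])
            if "dry_season_months" in s:
                s["dry_season_months"] = frozenset(s["dry_season_months"])
            d["site"] = SiteClimateSpec(**s)
        if isinstance(d.get("climate"), dict):
            c = dict(d["climate"])
            if "reduction_weeks" in c:
                c["reduction_weeks"] = tuple(tuple(w) for w in c["reduction_weeks"])
            d["climate"] = EnsembleClimateSpec(**c)
        if isinstance(d.get("sim"), dict):
            d["sim"] = SimConfig.from_dict(d["sim"])
        if isinstance(d.get("truth"), dict):
            d["truth"] = TraitAssemblage.from_dict(d["truth"])
        if isinstance(d.get("co2_modes"), list):
            d["co2_modes"] = tuple(d["co2_modes"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("output_dir", None)  # the science, not where it is written
        canon = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclasses.dataclass
class ExperimentResult:
    results: pd.DataFrame
    selection: object
    report: dict
    output_dir: Path


def _derived_seeds(seed: int, n: int = 6) -> list:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % (2**31 - 1)) for s in state]


def _round_floats(obj, ndigits=6):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return round(float(obj), ndigits)
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    return obj


def run_full_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Execute calibrate -> project -> analyze; see the module docstring."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = _derived_seeds(config.seed)
    stage = "setup"
    try:
        # ---- contemporary forcing and observations ----------------------
        stage = "forcing"
        if config.forcing_path:
            forcing = ForcingSeries.from_csv(config.forcing_path)
        else:
            forcing = generate_forcing(config.site, config.years, seed=seeds[0])
        stage = "observations"
        if config.observations_path:
            obs = ObservationSet.from_csv(config.observations_path)
            truth_out = None
        else:
            truth_out = simulate(config.truth, forcing, config.sim)
            obs = generate_observations(truth_out, config.sigma_log,
                                        seed=seeds[1])
        obs.to_csv(out_dir / "observations.csv")

        # ---- calibration -------------------------------------------------
        stage = "calibration"
        prior = PriorSpec()
        assemblages = sample_priors(prior, config.ensemble_size, seed=seeds[2])
        ensemble = TraitEnsemble.from_assemblages(assemblages)
        logger.info("simulating %d-member ensemble under contemporary forcing",
                    len(ensemble))
        contemporary_outputs = dict(zip(
            ensemble.ids, simulate_ensemble(ensemble, forcing, config.sim)))
        retained, drop_reasons = viability_filter(contemporary_outputs)
        if not retained:
            raise RuntimeError("no viable assemblages after filtering")
        logger.info("viability filter retained %d/%d members",
                    len(retained), len(ensemble))
        viable = ensemble.subset(retained)
        selection = select_assemblages(
            viable, contemporary_outputs, obs, prior,
            steps=config.mcmc_steps, burn_in=config.mcmc_burn_in,
            seed=seeds[3], method=config.selection_method)
        selection.save(out_dir / "selection.json", out_dir / "chain_trace.csv")
        selected = ensemble.subset(selection.selected_ids)
        selected.to_frame().to_csv(out_dir / "selected_traits.csv", index=False)

        # ---- projection --------------------------------------------------
        stage = "projection"
        climate_spec = dataclasses.replace(config.climate,
                                           n_models=config.n_climate_models)
        anomalies = generate_future_ensemble(climate_spec, seed=seeds[4])
        anomaly_sets_to_csv(anomalies, out_dir / "anomalies.csv")
        rows = []
        for aid in selection.selected_ids:
            summary = stress_indicators(contemporary_outputs[aid],
                                        ensemble.member(list(ensemble.ids).index(aid)))
            rows.append({"assemblage_id": aid, "climate_model": "observed",
                         "scenario": "contemporary",
                         "co2_mode": "contemporary", **summary.to_dict()})
        for anomaly in anomalies:
            for co2_mode in config.co2_modes:
                cell_forcing = apply_anomaly(forcing, anomaly, co2_mode)
                outs = simulate_ensemble(selected, cell_forcing, config.sim)
                for aid, out in zip(selection.selected_ids, outs):
                    summary = stress_indicators(
                        out, selected.member(list(selected.ids).index(aid)))
                    rows.append({"assemblage_id": aid,
                                 "climate_model": anomaly.model_name,
                                 "scenario": anomaly.scenario,
                                 "co2_mode": co2_mode, **summary.to_dict()})
                logger.info("projected %s / %s / %s", anomaly.model_name,
                            anomaly.scenario, co2_mode)
        results = pd.DataFrame(rows)
        expected = len(selection.selected_ids) * (
            1 + len(anomalies) * len(config.co2_modes))
        if len(results) != expected:
            raise RuntimeError(f"incomplete design: {len(results)} rows, "
                               f"expected {expected}")
        results.to_csv(out_dir / "results.csv", index=False)

        # ---- analysis ----------------------------------------------------
        stage = "analysis"
        report = _analyze(results, selected, selection, drop_reasons, config)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(_round_floats(report), fh, indent=2, sort_keys=True)

        stage = "manifest"
        manifest = {"config_hash": config.config_hash(), "seed": config.seed,
                    "version": __version__,
                    "timestamp": pd.Timestamp.now().isoformat()}
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception as exc:
        raise RuntimeError(f"experiment stage '{stage}' failed: {exc}") from exc
    return ExperimentResult(results=results, selection=selection,
                            report=report, output_dir=out_dir)


def _analyze(results: pd.DataFrame, selected: TraitEnsemble, selection,
             drop_reasons: dict, config: ExperimentConfig) -> dict:
    """Build the report: flux changes, failure risk, groups, regressions,
    variance decomposition. All numbers recomputable from results.csv."""
    future = results[results["scenario"] != "contemporary"]
    contemporary = results[results["scenario"] == "contemporary"]

    per_model = relative_change_table(results)
    ranges = {
        "gpp": across_model_range(per_model, "annual_gpp_change_pct")
        .to_dict(orient="records"),
        "et": across_model_range(per_model, "annual_et_change_pct")
        .to_dict(orient="records"),
    }

    plc = {}
    plc["contemporary_pct_days_plc60"] = 100.0 * contemporary["frac_days_plc60"].mean()
    plc["contemporary_pct_days_plc80"] = 100.0 * contemporary["frac_days_plc80"].mean()
    per_model_plc = (future.groupby(["climate_model", "scenario", "co2_mode"])
                     [["frac_days_plc60", "frac_days_plc80"]].mean() * 100.0)
    plc["per_model_pct_days"] = per_model_plc.reset_index().to_dict(orient="records")
    cell = per_model_plc.groupby(["scenario", "co2_mode"])
    plc["scenario_pct_days_plc60"] = {
        f"{s}|{c}": {"mean": g["frac_days_plc60"].mean(),
                     "min": g["frac_days_plc60"].min(),
                     "max": g["frac_days_plc60"].max()}
        for (s, c), g in cell}

    failed, safe = failure_group_split(results)
    groups = {"failed_ids": failed, "safe_ids": safe, "comparisons": {}}
    if failed and safe:
        by_assemblage = results.groupby("assemblage_id")
        m_tests = 3
        for metric in ("min_leaf_psi", "frac_days_below_p50gs",
                       "mean_transpiration"):
            agg = by_assemblage[metric].min() if metric == "min_leaf_psi" \
                else by_assemblage[metric].mean()
            u, raw, adj = group_comparison(agg.loc[failed], agg.loc[safe],
                                           m_tests=m_tests)
            groups["comparisons"][metric] = {
                "failed_mean": float(agg.loc[failed].mean()),
                "safe_mean": float(agg.loc[safe].mean()),
                "U": u, "p_raw": raw, "p_adjusted": adj}

    mean_plc60 = results.groupby("assemblage_id")["frac_days_plc60"].mean()
    if len(mean_plc60) >= 3:
        trait_frame = selected.to_frame().set_index("assemblage_id")
        trait_frame["hsm"] = results.groupby("assemblage_id")["hsm"].min()
        filtered, full = trait_regressions(
            trait_frame.loc[mean_plc60.index, list(TRAIT_FIELDS) + ["hsm"]]
            .rename_axis(None), mean_plc60.to_numpy())
        regressions = {"significant": filtered.to_dict(orient="records"),
                       "all": full.to_dict(orient="records")}
    else:
        regressions = {"significant": [], "all": [],
                       "note": "fewer than 3 selected assemblages"}

    decomposition = {}
    for response in ("frac_days_plc60", "annual_gpp", "annual_et"):
        decomposition[response] = variance_decomposition(
            future, response, factors=["assemblage_id", "climate_model",
                                       "scenario", "co2_mode"])

    return {
        "design": {"n_selected": len(selection.selected_ids),
                   "n_dropped": len(drop_reasons),
                   "n_climate_models": config.n_climate_models,
                   "years": config.years,
                   "co2_modes": list(config.co2_modes)},
        "flux_changes": {"per_model": per_model.to_dict(orient="records"),
                         "ranges": ranges},
        "hydraulic_failure": plc,
        "stress_groups": groups,
        "trait_regressions": regressions,
        "variance_decomposition_pct": decomposition,
        "leaf_stress": {
            "contemporary_min_leaf_psi": float(contemporary["min_leaf_psi"].mean()),
            "future_min_leaf_psi": float(future["min_leaf_psi"].mean())
            if len(future) else None,
            "contemporary_pct_days_below_p50gs":
                100.0 * contemporary["frac_days_below_p50gs"].mean(),
            "future_pct_days_below_p50gs":
                100.0 * future["frac_days_below_p50gs"].mean()
                if len(future) else None,
            "contemporary_mean_transpiration":
                float(contemporary["mean_transpiration"].mean()),
        },
    }
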