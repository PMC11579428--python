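"""Shared fixtures: synthetic forcing, reference runs, and output factories.

Expensive simulations are session-scoped and shared across test modules so
the suite stays within a desk-scale runtime.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hydrostand import (ForcingSeries, SimConfig, SiteClimateSpec,
                        generate_forcing, simulate)
from hydrostand.pipeline import DEFAULT_TRUTH
from hydrostand.simulate import SimulationOutput


@pytest.fixture(scope="session")
def site_spec() -> SiteClimateSpec:
    return SiteClimateSpec()


@pytest.fixture(scope="session")
def forcing_1yr(site_spec) -> ForcingSeries:
    return generate_forcing(site_spec, 1, seed=11)


@pytest.fixture(scope="session")
def forcing_3yr(site_spec) -> ForcingSeries:
    return generate_forcing(site_spec, 3, seed=42)


@pytest.fixture(scope="session")
def truth_output_1yr(forcing_1yr) -> SimulationOutput:
    return simulate(DEFAULT_TRUTH, forcing_1yr, SimConfig())


@pytest.fixture(scope="session")
def truth_output_3yr(forcing_3yr) -> SimulationOutput:
    return simulate(DEFAULT_TRUTH, forcing_3yr, SimConfig())


@pytest.fixture(scope="session")
def constant_day_forcing() -> ForcingSeries:
    """One identical rain-free day repeated for a year: idealized dry-down."""
    times = pd.date_range("2003-01-01", periods=365 * 24, freq="h")
    hour = times.hour.to_numpy()
    tair = 26.3 - 4.0 * np.cos(2 * np.pi * (hour - 14) / 24.0)
    sw = 800.0 * np.maximum(np.sin(np.pi * (hour - 6) / 12.0), 0.0)
    df = pd.DataFrame({
        "timestamp": times,
        "tair_C": tair,
        "precip_mm": 0.0,
        "swdown_Wm2": sw,
        "rh_pct": 70.0,
        "co2_ppm": 367.0,
    })
    return ForcingSeries(df)


@pytest.fixture(scope="session")
def micro_config(tmp_path_factory):
    """Smallest complete experiment: one model, one year, six members."""
    from hydrostand.pipeline import ExperimentConfig
    out = tmp_path_factory.mktemp("micro") / "run1"
    return ExperimentConfig(output_dir=str(out), seed=5, years=1,
                            ensemble_size=6, mcmc_steps=300, mcmc_burn_in=50,
                            n_climate_models=1)


@pytest.fixture(scope="session")
def micro_result(micro_config):
    from hydrostand.pipeline import run_full_experiment
    return run_full_experiment(micro_config)


@pytest.fixture(scope="session")
def smoke_result(tmp_path_factory):
    """The smoke-scale experiment: 20-member ensemble, 2 climate models,
    2 scenarios x 2 CO2 modes, 3 simulated years."""
    from hydrostand.pipeline import ExperimentConfig, run_full_experiment
    out = tmp_path_factory.mktemp("smoke") / "run"
    return run_full_experiment(
        ExperimentConfig.smoke(output_dir=str(out), seed=3))


@pytest.fixture()
def output_factory():
    """Build a SimulationOutput with prescribed daily values (no simulation)."""

    def make(days=365, start="2003-01-01", gpp=8.0, transpiration=1.0,
             soil_evap=0.3, runoff=0.5, drainage=2.0, swc=0.3,
             psi_leaf_min=-1.0, psi_stem_min=-0.8, plc_stem=0.1):
        idx = pd.date_range(start, periods=days, freq="D")

        def col(v):
            return np.broadcast_to(np.asarray(v, dtype=float), (days,)).copy()

        transp = col(transpiration)
        sevap = col(soil_evap)
        df = pd.DataFrame({
            "gpp": col(gpp), "transpiration": transp, "soil_evap": sevap,
            "et": transp + sevap, "runoff": col(runoff), "swc": col(swc),
            "psi_leaf_min": col(psi_leaf_min),
            "psi_stem_min": col(psi_stem_min), "plc_stem": col(plc_stem),
        }, index=pd.DatetimeIndex(idx, name="date"))
        return SimulationOutput(df, drainage=pd.Series(col(drainage), index=idx))

    return make
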