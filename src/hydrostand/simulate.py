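"""Static-stand plant-hydrodynamics simulator.

Hourly loop: coupled leaf exchange sets the transpiration demand, the
compartment chain (rhizosphere, absorbing roots, transporting roots, stem,
leaf) exchanges water down pressure gradients through vulnerability-scaled
conductances, and a single-layer soil bucket supplies the rhizosphere and
loses water to drainage, saturation-excess runoff and soil evaporation.
Outputs are aggregated to daily series. Stand structure and LAI are constant
throughout (no growth, no mortality removal).
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .config import SimConfig
from .forcing import ForcingSeries
from .network import Edge, Node, WaterNetwork
from .physiology import (JMAX_RATIO, PAR_PER_SW, RD_RATIO, _solve_leaf_core,
                         canopy_scale, farquhar_temp_responses,
                         pv_rwc_from_psi, pv_slope, pv_water_potential)
from .traits import TraitAssemblage, TraitEnsemble

logger = logging.getLogger(__name__)

MM_H_PER_MMOL = 0.018 * 3600.0 / 1000.0  # mm h-1 per (mmol H2O m-2 s-1)
MPA_PER_M = 0.00981                       # gravity head per meter of height
GC_PER_UMOL = 12.011e-6                   # g C per umol CO2

COMPARTMENTS = ("rhizosphere", "absorbing_root", "transporting_root",
                "stem", "leaf")
OUTPUT_COLUMNS = ["gpp", "transpiration", "soil_evap", "et", "runoff", "swc",
                  "psi_leaf_min", "psi_stem_min", "plc_stem"]
_N_SOIL, _N_RHIZ, _N_AROOT, _N_TROOT, _N_STEM, _N_LEAF = range(6)


def _vuln(psi, p50, shape):
    # unchecked sigmoid for the inner loop; public checks live in physiology
    return 1.0 / (1.0 + (np.minimum(psi, 0.0) / p50) ** shape)


class SimulationOutput:
    """Daily output series for one assemblage, plus water-balance bookkeeping."""

    def __init__(self, df: pd.DataFrame, drainage: pd.Series | None = None,
                 water_balance: dict | None = None, clamp_count: int = 0):
        self.df = df
        self.drainage = drainage
        self.water_balance = water_balance or {}
        self.clamp_count = clamp_count

    def to_csv(self, path) -> None:
        out = self.df[OUTPUT_COLUMNS].copy()
        out.index.name = "date"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "SimulationOutput":
        df = pd.read_csv(path, index_col="date", parse_dates=["date"])
        return cls(df)

    def monthly_observables(self) -> pd.DataFrame:
        """Monthly ET (mm), GPP (g C m-2), mean SWC (m3 m-3) and catchment
        outflow 'runoff' (surface runoff + deep drainage, mm)."""
        df = self.df.copy()
        if self.drainage is not None:
            df["outflow"] = df["runoff"] + self.drainage
        else:
            df["outflow"] = df["runoff"]
        per = df.index.to_period("M")
        g = df.groupby(per)
        return pd.DataFrame({
            "et": g["et"].sum(),
            "gpp": g["gpp"].sum(),
            "swc": g["swc"].mean(),
            "runoff": g["outflow"].sum(),
        })

    def annual_totals(self) -> pd.DataFrame:
        g = self.df.groupby(self.df.index.year)
        return pd.DataFrame({"gpp": g["gpp"].sum(), "et": g["et"].sum(),
                             "transpiration": g["transpiration"].sum()})


@dataclasses.dataclass
class PlantSoilState:
    """Evolving water state: compartment contents plus soil store."""

    W: np.ndarray                 # (6, M) contents in mm: soil, rhiz, ..., leaf
    traits: TraitEnsemble
    config: SimConfig
    cum_runoff: np.ndarray | float = 0.0
    cum_drainage: np.ndarray | float = 0.0

    def network(self) -> WaterNetwork:
        return build_network(self.traits, self.config)

    def potentials(self) -> dict:
        net = self.network()
        psi = net.potentials(self.W)
        return {"soil": psi[_N_SOIL],
                **{name: psi[i + 1] for i, name in enumerate(COMPARTMENTS)}}

    def relative_water_content(self) -> dict:
        vols = _compartment_volumes(self.traits, self.config)
        return {name: self.W[i + 1] / vols[i] for i, name in enumerate(COMPARTMENTS)}

    @property
    def soil_theta(self):
        return self.W[_N_SOIL] / self.config.soil.capacity_mm * self.config.soil.theta_sat


def _compartment_volumes(traits: TraitEnsemble, cfg: SimConfig) -> list:
    """Saturated water content (mm) of rhiz, aroot, troot, stem, leaf."""
    m = len(traits)
    ones = np.ones(m)
    v_stem = traits.column("theta_sat_stem") * cfg.wood_volume_mm
    lma = 1.0 / traits.column("sla")  # g m-2 leaf
    v_leaf = (cfg.lai * lma * cfg.leaf_water_per_dry_mass / 1000.0
              + cfg.v_leaf_base_mm)  # mm, leaf lamina plus twig/branch buffer
    return [cfg.v_rhiz_mm * ones, cfg.v_aroot_mm * ones, cfg.v_troot_mm * ones,
            v_stem, v_leaf]


def build_network(traits: TraitEnsemble, cfg: SimConfig) -> WaterNetwork:
    """Assemble the six-node soil/plant water network for a trait batch."""
    soil = cfg.soil
    m = len(traits)
    vols = _compartment_volumes(traits, cfg)
    pi0 = traits.column("pi0")
    eps = traits.column("eps_bulk")
    rf = traits.column("resid_frac_stem")
    cap = traits.column("cap_frac")
    margin = cfg.rwc_clamp_margin
    # psi floor keeps gradients finite: the normalized content where the
    # (solute-only) potential reaches psi_floor bounds the state space, well
    # above the residual-content pole
    rwcs_floor = np.maximum(pi0 / cfg.psi_floor, margin)
    rwc_floor = rf + rwcs_floor * (1.0 - rf)
    rel_floor = float((soil.psi_sat / cfg.psi_floor) ** (1.0 / soil.b))

    def plant_node(name, vol):
        def psi_of(W):
            return pv_water_potential(np.clip(W / vol, rwc_floor, 1.0),
                                      pi0, eps, rf, cap)

        def cap_of(W):
            rwc = np.clip(W / vol, rwc_floor, 1.0)
            return vol / pv_slope(rwc, pi0, eps, rf, cap)

        return Node(name, psi_of, cap_of,
                    w_min=vol * rwc_floor, w_max=vol)

    def retention_node(name, capacity):
        def psi_of(W):
            rel = np.clip(W / capacity, rel_floor, 1.0)
            return soil.psi_sat * rel ** (-soil.b)

        def cap_of(W):
            rel = np.clip(W / capacity, rel_floor, 1.0)
            psi = soil.psi_sat * rel ** (-soil.b)
            return capacity * rel / (soil.b * np.abs(psi))

        return Node(name, psi_of, cap_of,
                    w_min=capacity * rel_floor,
                    w_max=capacity * np.ones(m) if np.ndim(capacity) == 0 else capacity)

    nodes = [
        retention_node("soil", soil.capacity_mm),
        retention_node("rhizosphere", cfg.v_rhiz_mm),
        plant_node("absorbing_root", vols[1]),
        plant_node("transporting_root", vols[2]),
        plant_node("stem", vols[3]),
        plant_node("leaf", vols[4]),
    ]

    k_seg = traits.column("kmax_plant") * MM_H_PER_MMOL * cfg.lai * 4.0
    taper = cfg.height_m ** (-traits.column("taper_exp"))
    srl_scale = traits.column("srl") / cfg.srl_ref
    p50_s, a_s = traits.column("p50_stem"), traits.column("shape_stem")
    p50_r, a_r = traits.column("p50_root"), traits.column("shape_root")
    upstream = cfg.vulnerability_at == "upstream"

    def pair_psi(pi_up, pj_down):
        return pi_up if upstream else 0.5 * (pi_up + pj_down)

    def soil_interface(pi_up, pj_down):
        # upwind (soil-side) conductivity: a transiently dry rhizosphere
        # shell must not choke its own rewetting from a moist bulk soil
        rel = np.maximum(pi_up / soil.psi_sat, 1.0)
        k_rel = rel ** (-(2.0 * soil.b + 3.0) / soil.b)
        return cfg.soil_interface_factor * k_seg * k_rel

    def root_edge(scale):
        def K(pi_up, pj_down):
            return scale * _vuln(pair_psi(pi_up, pj_down), p50_r, a_r)
        return K

    def stem_edge():
        def K(pi_up, pj_down):
            return k_seg * taper * _vuln(pair_psi(pi_up, pj_down), p50_s, a_s)
        return K

    head = MPA_PER_M * cfg.height_m / 2.0
    edges = [
        Edge(_N_SOIL, _N_RHIZ, soil_interface),
        Edge(_N_RHIZ, _N_AROOT, root_edge(k_seg * srl_scale)),
        Edge(_N_AROOT, _N_TROOT, root_edge(k_seg)),
        Edge(_N_TROOT, _N_STEM, stem_edge(), head=head),
        Edge(_N_STEM, _N_LEAF, stem_edge(), head=head),
    ]

    # fused evaluators: same physics as the per-node/per-edge callables,
    # computed in a handful of vectorized calls for the hourly loop
    v4 = np.stack(vols[1:])                       # aroot, troot, stem, leaf
    ret_caps = np.array([soil.capacity_mm, cfg.v_rhiz_mm])
    ret_min = np.array([rel_floor, rel_floor])
    has_cap = bool(np.any(cap > 0))
    cap_safe = np.maximum(cap, 1e-12)
    boundary = 1.0 - cap
    psi_ft = pi0 / np.maximum(boundary, 1e-12) \
        + np.maximum(-pi0 + eps * (boundary - 1.0), 0.0)

    def eval_state(W):
        relr = np.clip(W[:2] / ret_caps[:, None], ret_min[:, None], 1.0)
        psir = soil.psi_sat * relr ** (-soil.b)
        capr = ret_caps[:, None] * relr / (soil.b * np.abs(psir))
        rwc = np.clip(W[2:] / v4, rwc_floor, 1.0)
        rwcs = (rwc - rf) / (1.0 - rf)
        turg = -pi0 + eps * (rwcs - 1.0)
        psip = pi0 / rwcs + np.maximum(turg, 0.0)
        slope = (-pi0 / (rwcs * rwcs) + np.where(turg > 0.0, eps, 0.0))
        if has_cap:
            in_cap = (cap > 0) & (rwcs >= boundary)
            psip = np.where(in_cap, psi_ft * (1.0 - rwcs) / cap_safe, psip)
            slope = np.where(in_cap, -psi_ft / cap_safe, slope)
        capp = v4 * (1.0 - rf) / slope
        return (np.concatenate([psir, psip]), np.concatenate([capr, capp]))

    p50v = np.stack([p50_r, p50_r, p50_s, p50_s])
    shapev = np.stack([a_r, a_r, a_s, a_s])
    scalev = np.stack([k_seg * srl_scale, k_seg, k_seg * taper, k_seg * taper])
    k_rel_exp = -(2.0 * soil.b + 3.0) / soil.b
    up_idx = np.array([1, 2, 3, 4])
    down_idx = np.array([2, 3, 4, 5])

    def edge_conds(psi):
        rel0 = np.maximum(psi[_N_SOIL] / soil.psi_sat, 1.0)
        k0 = cfg.soil_interface_factor * k_seg * rel0 ** k_rel_exp
        pe = psi[up_idx] if upstream else 0.5 * (psi[up_idx] + psi[down_idx])
        kv = scalev / (1.0 + (np.minimum(pe, 0.0) / p50v) ** shapev)
        return [k0, kv[0], kv[1], kv[2], kv[3]]

    return WaterNetwork(nodes, edges, max_frac_change=cfg.max_frac_change,
                        max_substeps=cfg.max_substeps,
                        eval_state=eval_state, edge_conds=edge_conds)


def initial_state(traits: TraitEnsemble, cfg: SimConfig) -> PlantSoilState:
    """Start from a moist soil with the plant in hydrostatic equilibrium."""
    soil = cfg.soil
    m = len(traits)
    vols = _compartment_volumes(traits, cfg)
    theta_rel = soil.theta_init_rel
    psi_soil = soil.psi_sat * theta_rel ** (-soil.b)
    head = MPA_PER_M * cfg.height_m / 2.0
    targets = [psi_soil, psi_soil, psi_soil, psi_soil - head, psi_soil - 2 * head]
    pi0 = traits.column("pi0")
    eps = traits.column("eps_bulk")
    rf = traits.column("resid_frac_stem")
    cap = traits.column("cap_frac")
    W = np.empty((6, m))
    W[_N_SOIL] = theta_rel * soil.capacity_mm
    W[_N_RHIZ] = theta_rel * cfg.v_rhiz_mm
    for i, (vol, tgt) in enumerate(zip(vols[1:], targets[1:]), start=2):
        rwc = pv_rwc_from_psi(np.full(m, tgt), pi0, eps, rf, cap)
        W[i] = rwc * vol
    return PlantSoilState(W=W, traits=traits, config=cfg)


def step_water_fluxes(state: PlantSoilState, transpiration_demand, precip_mm_h,
                      dt_h, soil_evap_potential=0.0,
                      free_drainage: bool = True):
    """Advance the water state by one step of ``dt_h`` hours.

    ``transpiration_demand`` (mm h-1) is drawn from the leaf; ``precip_mm_h``
    infiltrates into the soil (saturation excess becomes runoff). Returns
    ``(new_state, fluxes)`` where fluxes reports the applied totals in mm.
    """
    if dt_h <= 0:
        raise ValueError("dt must be positive")
    cfg = state.config
    soil = cfg.soil
    net = state.network()
    demand = np.broadcast_to(np.asarray(transpiration_demand, float),
                             state.W[_N_LEAF].shape)

    def ext_fn(W, psi):
        rel = np.clip(W[_N_SOIL] / soil.capacity_mm, 0.0, 1.0)
        fluxes = [("infiltration", _N_SOIL,
                   np.broadcast_to(float(precip_mm_h), W[_N_SOIL].shape)),
                  ("transpiration", _N_LEAF, -demand)]
        if free_drainage:
            fluxes.append(("drainage", _N_SOIL,
                           -soil.k_sat * rel ** (2.0 * soil.b + 3.0)))
        if np.any(np.asarray(soil_evap_potential) > 0):
            fluxes.append(("soil_evap", _N_SOIL,
                           -np.asarray(soil_evap_potential) * rel))
        return fluxes

    W_new, totals, n_sub, n_clamp = net.step(state.W, dt_h, ext_fn)
    runoff = totals.get("overflow_soil", 0.0)
    drainage = -totals.get("drainage", 0.0)
    new_state = PlantSoilState(W=W_new, traits=state.traits, config=cfg,
                               cum_runoff=state.cum_runoff + runoff,
                               cum_drainage=state.cum_drainage + drainage)
    return new_state, totals


def simulate_ensemble(traits: TraitEnsemble, forcing: ForcingSeries,
                      config: SimConfig | None = None, seed: int = 0):
    """Run the hourly loop for a batch of assemblages under shared forcing.

    Returns a list of :class:`SimulationOutput`, one per ensemble member, in
    ensemble order. Deterministic given (traits, forcing, seed); the model
    itself has no stochastic components, the seed is recorded for provenance.
    """
    cfg = config or SimConfig()
    forcing.validate()
    if forcing.step != pd.Timedelta(hours=1):
        raise ValueError("simulator expects hourly forcing")
    if not forcing.whole_years():
        raise ValueError("forcing must span at least one whole calendar year")

    df = forcing.df
    n_t = len(df)
    if n_t % 24 != 0:
        raise ValueError("forcing must cover whole days")
    m = len(traits)
    tair = df["tair_C"].to_numpy()
    precip = df["precip_mm"].to_numpy()
    sw = df["swdown_Wm2"].to_numpy()
    rh = df["rh_pct"].to_numpy()
    co2 = df["co2_ppm"].to_numpy()
    vpd = forcing.vpd_kpa()
    hours = df["timestamp"].dt.hour.to_numpy()
    day_idx = np.arange(n_t) // 24
    n_days = n_t // 24
    dates = df["timestamp"].iloc[::24].dt.normalize().reset_index(drop=True)

    g0 = traits.column("g0")
    g1 = traits.column("g1")
    vcmax25 = traits.column("vcmax25")
    p50_gs = traits.column("p50_gs")
    a_gs = traits.column("a_gs")
    p50_s = traits.column("p50_stem")
    shape_s = traits.column("shape_stem")
    scale = canopy_scale(cfg.lai, cfg.k_ext)
    # temperature-dependent biochemistry, precomputed for every timestep
    fv_t, fj_t, fr_t, kc_t, gstar_t = farquhar_temp_responses(tair)
    par_t = np.maximum(sw, 0.0) * PAR_PER_SW
    hs_t = np.clip(rh / 100.0, 0.05, 1.0)
    cs_t = co2 * 1e-6 * cfg.patm
    e_conv = 0.018 * 3600.0 / (cfg.patm / 1000.0)  # gs*vpd -> mm h-1

    state = initial_state(traits, cfg)
    net = build_network(traits, cfg)
    W = state.W
    soil = cfg.soil
    psi = net.potentials(W)

    daily = {k: np.zeros((n_days, m)) for k in
             ("gpp", "transpiration", "soil_evap", "runoff", "drainage")}
    psi_leaf_min = np.full((n_days, m), np.inf)
    psi_stem_min = np.full((n_days, m), np.inf)
    plc_max = np.zeros((n_days, m))
    swc_sum = np.zeros((n_days, m))
    clamp_added = np.zeros(m)
    n_clamp_total = 0
    w_start_total = W.sum(axis=0)
    swc_capacity = soil.capacity_mm + cfg.v_rhiz_mm

    from .soil import soil_evaporation

    for t in range(n_t):
        beta = 1.0 / (1.0 + (np.minimum(psi[_N_LEAF], 0.0) / p50_gs) ** a_gs)
        rd = RD_RATIO * vcmax25 * fr_t[t]
        if par_t[t] <= 1e-9:
            an_leaf, gs_leaf = -rd, g0
        else:
            an_leaf, gs_leaf, _ci = _solve_leaf_core(
                par_t[t], cs_t[t], hs_t[t], beta, g0, g1,
                vcmax25 * fv_t[t], JMAX_RATIO * vcmax25 * fj_t[t],
                rd, kc_t[t], gstar_t[t], cfg.patm)
        e_demand = gs_leaf * scale * vpd[t] * e_conv
        gpp_inst = np.maximum(an_leaf + rd, 0.0) * scale

        precip_rate = precip[t]  # mm over the hourly step
        e_soil_pot = soil_evaporation(sw[t], tair[t], 1.0, cfg.lai, cfg.k_ext)

        def ext_fn(Wc, psic, _p=precip_rate, _ed=e_demand, _es=e_soil_pot):
            rel = np.clip(Wc[_N_SOIL] / soil.capacity_mm, 0.0, 1.0)
            fluxes = [("infiltration", _N_SOIL,
                       np.full(m, _p)),
                      ("drainage", _N_SOIL,
                       -soil.k_sat * rel ** (2.0 * soil.b + 3.0)),
                      ("transpiration", _N_LEAF, -_ed)]
            if _es > 0:
                fluxes.append(("soil_evap", _N_SOIL, -_es * rel))
            return fluxes

        W, totals, _n_sub, n_clamp = net.step(W, 1.0, ext_fn)
        n_clamp_total += n_clamp
        psi = net.potentials(W)

        d = day_idx[t]
        daily["gpp"][d] += gpp_inst * 3600.0 * GC_PER_UMOL
        daily["transpiration"][d] += -totals.get("transpiration", 0.0)
        daily["soil_evap"][d] += -totals.get("soil_evap", 0.0)
        daily["runoff"][d] += totals.get("overflow_soil", 0.0)
        daily["drainage"][d] += -totals.get("drainage", 0.0)
        for key, val in totals.items():
            if key.startswith("clamp_"):
                clamp_added += val
        if 10 <= hours[t] <= 14:
            psi_leaf_min[d] = np.minimum(psi_leaf_min[d], psi[_N_LEAF])
        psi_stem_min[d] = np.minimum(psi_stem_min[d], psi[_N_STEM])
        plc_max[d] = np.maximum(plc_max[d], 1.0 - _vuln(psi[_N_STEM], p50_s, shape_s))
        swc_sum[d] += (W[_N_SOIL] + W[_N_RHIZ]) / swc_capacity * soil.theta_sat

    # no 10:00-14:00 sample can only happen with sub-daily gaps, guarded above
    psi_leaf_min = np.where(np.isfinite(psi_leaf_min), psi_leaf_min, 0.0)

    if n_clamp_total:
        logger.info("simulate: %d residual-content clamps applied", n_clamp_total)

    et = daily["transpiration"] + daily["soil_evap"]
    precip_member = np.full(m, precip.sum())
    delta_storage = W.sum(axis=0) - w_start_total
    balance_err = (precip_member + clamp_added - delta_storage
                   - daily["runoff"].sum(axis=0) - daily["drainage"].sum(axis=0)
                   - et.sum(axis=0))

    outputs = []
    for i in range(m):
        out_df = pd.DataFrame({
            "gpp": daily["gpp"][:, i],
            "transpiration": daily["transpiration"][:, i],
            "soil_evap": daily["soil_evap"][:, i],
            "et": et[:, i],
            "runoff": daily["runoff"][:, i],
            "swc": swc_sum[:, i] / 24.0,
            "psi_leaf_min": psi_leaf_min[:, i],
            "psi_stem_min": psi_stem_min[:, i],
            "plc_stem": plc_max[:, i],
        }, index=pd.DatetimeIndex(dates, name="date"))
        wb = {"precip": float(precip_member[i]),
              "delta_storage": float(delta_storage[i]),
              "runoff": float(daily["runoff"][:, i].sum()),
              "drainage": float(daily["drainage"][:, i].sum()),
              "et": float(et[:, i].sum()),
              "clamp_added": float(clamp_added[i]),
              "residual": float(balance_err[i])}
        outputs.append(SimulationOutput(
            out_df, drainage=pd.Series(daily["drainage"][:, i], index=out_df.index),
            water_balance=wb, clamp_count=n_clamp_total))
    return outputs


def simulate(assemblage: TraitAssemblage, forcing: ForcingSeries,
             config: SimConfig | None = None, seed: int = 0) -> SimulationOutput:
    """Simulate a single trait assemblage; see :func:`simulate_ensemble`."""
    ens = TraitEnsemble.from_assemblages([assemblage])
    return simulate_ensemble(ens, forcing, config=config, seed=seed)[0]
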