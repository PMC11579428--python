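"""Trait-ensemble calibration against monthly observations.

The workflow mirrors ensemble filtering as practiced with expensive stand
simulators: sample a Latin-hypercube prior ensemble, simulate each member
once under contemporary forcing, drop nonviable members (no-growth or lethal
conductivity loss), then select the observation-consistent subset with a
post hoc Markov chain over the precomputed runs. Proposals are drawn from
the prior and mapped to the nearest ensemble member in standardized trait
space by Mahalanobis distance; moves are accepted by the Metropolis rule on
the multivariate log-normal observation likelihood.
"""
from __future__ import annotations

import dataclasses
import json
import math
import warnings

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .simulate import SimulationOutput
from .traits import TRAIT_FIELDS, TraitAssemblage, TraitEnsemble

GPP_MIN_VIABLE = 200.0   # g C m-2 yr-1, no-growth threshold
PLC_LETHAL = 0.80        # daily max stem PLC at or above this is lethal


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class PriorRange:
    lower: float
    upper: float
    dist: str = "uniform"  # or "log-uniform"


DEFAULT_PRIORS: dict = {
    "p50_stem": PriorRange(-6.0, -1.5),
    "shape_stem": PriorRange(1.0, 6.0),
    "p50_root": PriorRange(-5.0, -1.0),
    "shape_root": PriorRange(1.0, 6.0),
    "p50_gs": PriorRange(-3.5, -1.0),
    "a_gs": PriorRange(1.0, 6.0),
    "g0": PriorRange(0.005, 0.04, "log-uniform"),
    "g1": PriorRange(4.0, 12.0),
    "theta_sat_stem": PriorRange(0.3, 0.7),
    "resid_frac_stem": PriorRange(0.1, 0.5),
    "pi0": PriorRange(-2.5, -0.8),
    "eps_bulk": PriorRange(5.0, 20.0),
    "cap_frac": PriorRange(0.0, 0.08),
    "kmax_plant": PriorRange(1.0, 16.0, "log-uniform"),
    "taper_exp": PriorRange(0.0, 0.5),
    "srl": PriorRange(5.0, 60.0),
    "sla": PriorRange(0.008, 0.035),
    "vcmax25": PriorRange(25.0, 80.0),
}


class PriorSpec:
    """Per-trait bounds and distribution tags covering every trait field."""

    def __init__(self, ranges: dict | None = None):
        self.ranges = dict(DEFAULT_PRIORS if ranges is None else ranges)
        self.validate()

    def validate(self) -> None:
        for name in TRAIT_FIELDS:
            if name not in self.ranges:
                raise ValueError(f"prior spec missing trait '{name}'")
            r = self.ranges[name]
            if not r.lower < r.upper:
                raise ValueError(f"prior for trait '{name}': lower must be "
                                 f"below upper ({r.lower} >= {r.upper})")
            if r.dist == "log-uniform" and r.lower <= 0:
                raise ValueError(f"prior for trait '{name}': log-uniform "
                                 "requires positive bounds")
            if r.dist not in ("uniform", "log-uniform"):
                raise ValueError(f"prior for trait '{name}': unknown "
                                 f"distribution '{r.dist}'")

    def _transform(self, u: np.ndarray) -> np.ndarray:
        """Map unit-cube samples (n, d) to trait values."""
        out = np.empty_like(u)
        for k, name in enumerate(TRAIT_FIELDS):
            r = self.ranges[name]
            if r.dist == "log-uniform":
                out[:, k] = np.exp(np.log(r.lower)
                                   + u[:, k] * (np.log(r.upper) - np.log(r.lower)))
            else:
                out[:, k] = r.lower + u[:, k] * (r.upper - r.lower)
        return out

    def midpoints(self) -> np.ndarray:
        return np.array([(self.ranges[n].lower + self.ranges[n].upper) / 2.0
                         for n in TRAIT_FIELDS])

    def half_ranges(self) -> np.ndarray:
        return np.array([(self.ranges[n].upper - self.ranges[n].lower) / 2.0
                         for n in TRAIT_FIELDS])

    def standardize(self, values: np.ndarray) -> np.ndarray:
        return (values - self.midpoints()) / self.half_ranges()

    def sample_plain(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self._transform(rng.random((n, len(TRAIT_FIELDS))))

    def to_yaml(self, path) -> None:
        import yaml
        data = {name: {"lower": r.lower, "upper": r.upper, "dist": r.dist}
                for name, r in self.ranges.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PriorSpec":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls({name: PriorRange(float(v["lower"]), float(v["upper"]),
                                     v.get("dist", "uniform"))
                    for name, v in data.items()})


def sample_priors(spec: PriorSpec, n: int, seed: int) -> list:
    """Latin-hypercube sample of n trait assemblages (one per stratum and
    trait); reproducible under the seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    sampler = qmc.LatinHypercube(d=len(TRAIT_FIELDS), seed=seed)
    values = spec._transform(sampler.random(n))
    return [TraitAssemblage(**dict(zip(TRAIT_FIELDS, row))) for row in values]


# ---------------------------------------------------------------------------
# Observations and likelihood
# ---------------------------------------------------------------------------

OBS_VARIABLES = ("et", "gpp", "swc", "runoff")


class ObservationSet:
    """Monthly observation summaries with log-scale error estimates.

    Long-format table with columns ``month, variable, value, sigma_log``;
    months must align across the four variables and all values must be
    positive (log-normal support).
    """

    def __init__(self, df: pd.DataFrame):
        required = {"month", "variable", "value", "sigma_log"}
        if not required.issubset(df.columns):
            raise ValueError(f"observation table needs columns {sorted(required)}")
        self.df = df.copy()
        self.df["month"] = self.df["month"].astype(str)
        self.validate()

    def validate(self) -> None:
        if (self.df["value"] <= 0).any():
            raise ValueError("observation values must be positive")
        if (self.df["sigma_log"] <= 0).any():
            raise ValueError("sigma_log must be positive")
        month_sets = {v: set(g["month"]) for v, g in self.df.groupby("variable")}
        ref = None
        for v, months in month_sets.items():
            if ref is None:
                ref = months
            elif months != ref:
                raise ValueError("months are not aligned across variables")

    def months(self) -> list:
        return sorted(set(self.df["month"]))

    def pivot(self, field: str = "value") -> pd.DataFrame:
        return self.df.pivot_table(index="month", columns="variable",
                                   values=field, aggfunc="first").sort_index()

    def to_csv(self, path) -> None:
        self.df[["month", "variable", "value", "sigma_log"]].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ObservationSet":
        return cls(pd.read_csv(path))


def mahalanobis(x, center, cov, jitter: float = 0.0) -> float:
    """Mahalanobis distance sqrt((x-c)^T cov^-1 (x-c)).

    ``cov`` must be symmetric positive-definite; a singular covariance raises
    with a suggestion to pass a ridge ``jitter`` (added to the diagonal).
    """
    x = np.asarray(x, dtype=float)
    center = np.asarray(center, dtype=float)
    cov = np.asarray(cov, dtype=float) + jitter * np.eye(len(x))
    if x.shape != center.shape or cov.shape != (len(x), len(x)):
        raise ValueError("dimension mismatch")
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance is singular or not positive-definite; "
                         "consider a ridge regularization (jitter > 0)") from exc
    y = np.linalg.solve(L, x - center)
    return float(np.sqrt(y @ y))


_SIM_FLOOR = 1e-6


def log_likelihood(output: SimulationOutput, obs: ObservationSet) -> float:
    """Log-likelihood of a run's monthly aggregates under the observations.

    Diagonal multivariate log-normal: sum over months and variables of the
    Normal(log(observed), sigma_log^2) log-density evaluated at
    log(simulated). Simulated values are floored at a small epsilon with a
    warning to stay inside the log-normal support.
    """
    sim = output.monthly_observables()
    sim.index = sim.index.astype(str)
    obs_v = obs.pivot("value")
    obs_s = obs.pivot("sigma_log")
    missing = [mth for mth in obs_v.index if mth not in sim.index]
    if missing:
        raise ValueError(f"simulated output lacks observed months: {missing}")
    total = 0.0
    for var in OBS_VARIABLES:
        s = sim.loc[obs_v.index, var].to_numpy(dtype=float)
        if np.any(s <= 0):
            warnings.warn(f"non-positive simulated {var} floored at {_SIM_FLOOR}",
                          stacklevel=2)
            s = np.maximum(s, _SIM_FLOOR)
        mu = np.log(obs_v[var].to_numpy(dtype=float))
        sig = obs_s[var].to_numpy(dtype=float)
        z = (np.log(s) - mu) / sig
        total += float(np.sum(-np.log(sig * math.sqrt(2.0 * math.pi)) - 0.5 * z * z))
    if not np.isfinite(total):
        raise ValueError("non-finite log-likelihood")
    return total


# ---------------------------------------------------------------------------
# Viability filter and MCMC selection
# ---------------------------------------------------------------------------


def viability_filter(outputs: dict, gpp_min: float = GPP_MIN_VIABLE,
                     plc_lethal: float = PLC_LETHAL):
    """Drop no-growth and hydraulically dead members.

    ``outputs`` maps assemblage id to its contemporary SimulationOutput.
    Returns (retained ids sorted, drop reasons dict id -> reason).
    """
    retained, reasons = [], {}
    for aid in sorted(outputs):
        out = outputs[aid]
        annual_gpp = float(out.annual_totals()["gpp"].mean())
        max_plc = float(out.df["plc_stem"].max())
        if annual_gpp < gpp_min:
            reasons[aid] = f"no-growth (annual GPP {annual_gpp:.1f} < {gpp_min})"
        elif max_plc >= plc_lethal:
            reasons[aid] = f"lethal PLC (max {max_plc:.2f} >= {plc_lethal})"
        else:
            retained.append(aid)
    return retained, reasons


@dataclasses.dataclass
class SelectionResult:
    selected_ids: list
    trace: pd.DataFrame              # step, current_id, proposed_id, accepted, log_likelihood
    intervals: pd.DataFrame          # trait, lower, upper
    settings: dict

    def interval(self, trait: str) -> tuple:
        row = self.intervals[self.intervals["trait"] == trait].iloc[0]
        return float(row["lower"]), float(row["upper"])

    def save(self, manifest_path, trace_path) -> None:
        with open(manifest_path, "w") as fh:
            json.dump({"settings": self.settings,
                       "selected_ids": [int(i) for i in self.selected_ids],
                       "intervals": {r["trait"]: [r["lower"], r["upper"]]
                                     for _, r in self.intervals.iterrows()}},
                      fh, indent=2, sort_keys=True)
        self.trace.to_csv(trace_path, index=False)


def _trait_intervals(values: np.ndarray, ids: list) -> pd.DataFrame:
    rows = []
    for k, name in enumerate(TRAIT_FIELDS):
        col = values[:, k]
        rows.append({"trait": name,
                     "lower": float(np.percentile(col, 2.5)),
                     "upper": float(np.percentile(col, 97.5))})
    return pd.DataFrame(rows)


def select_assemblages(ensemble: TraitEnsemble, outputs: dict,
                       obs: ObservationSet, prior: PriorSpec,
                       steps: int = 20000, burn_in: int = 10000,
                       seed: int = 0, method: str = "mcmc",
                       keep_fraction: float = 0.95,
                       cov_jitter: float = 1e-6,
                       temperature: float | str = "per-term") -> SelectionResult:
    """Select observation-consistent assemblages from a precomputed ensemble.

    method "mcmc": Markov chain over ensemble members. Each proposal draws a
    trait vector from the prior and maps it to the nearest viable member by
    Mahalanobis distance in standardized trait space; moves are accepted with
    probability min(1, exp(delta log-likelihood / T)). The default
    ``temperature`` "per-term" sets T to the number of observation terms
    (months x variables), i.e. moves are compared on the geometric-mean
    per-observation likelihood. A finite ensemble under an untempered
    many-month product likelihood degenerates onto the single best run;
    tempering keeps the chain mixing across the observation-consistent part
    of the ensemble so the retained set reflects the observations and their
    errors rather than one run. Pass ``temperature=1.0`` for the raw rule.

    After burn-in, the distinct visited members ranked by (raw) likelihood
    are truncated to the top ``keep_fraction`` by count ("95% of selected
    models"), and per-trait 95% intervals are taken across the selected
    members.

    method "ranking": no chain; all viable members ranked by likelihood and
    truncated the same way (importance-ranking cross-check).
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    if steps <= burn_in:
        raise ValueError("steps must exceed burn_in")
    ids = list(ensemble.ids)
    logl = np.array([log_likelihood(outputs[i], obs) for i in ids])
    n_terms = len(obs.months()) * len(OBS_VARIABLES)
    temp = float(n_terms) if temperature == "per-term" else float(temperature)
    if temp <= 0:
        raise ValueError("temperature must be positive")
    settings = {"steps": steps, "burn_in": burn_in, "seed": seed,
                "method": method, "keep_fraction": keep_fraction,
                "temperature": temp, "n_ensemble": len(ids)}

    if method == "ranking":
        order = np.argsort(-logl, kind="stable")
        n_keep = max(1, math.ceil(keep_fraction * len(ids)))
        sel_pos = sorted(order[:n_keep], key=lambda p: ids[p])
        selected = [ids[p] for p in sel_pos]
        intervals = _trait_intervals(ensemble.values[sel_pos], selected)
        trace = pd.DataFrame({"step": [], "current_id": [], "proposed_id": [],
                              "accepted": [], "log_likelihood": []})
        return SelectionResult(selected, trace, intervals, settings)
    if method != "mcmc":
        raise ValueError("method must be 'mcmc' or 'ranking'")

    rng = np.random.default_rng(seed)
    z = prior.standardize(ensemble.values)
    cov = np.cov(z, rowvar=False) + cov_jitter * np.eye(z.shape[1])
    vi = np.linalg.inv(cov)
    id_arr = np.asarray(ids)

    def nearest_member(z_prop: np.ndarray) -> int:
        diff = z - z_prop
        d2 = np.einsum("ij,jk,ik->i", diff, vi, diff)
        best = np.flatnonzero(d2 == d2.min())
        # deterministic tie-break on assemblage id keeps selection invariant
        # to the storage order of ensemble members
        return int(best[np.argmin(id_arr[best])])

    cur = int(np.argmin(id_arr))  # start at the lowest id: order-invariant
    rows = []
    accepted_post = 0
    for step in range(steps):
        z_prop = prior.standardize(prior.sample_plain(1, rng))[0]
        prop = nearest_member(z_prop)
        accept = math.log(rng.random()) < (logl[prop] - logl[cur]) / temp
        if accept:
            cur = prop
            if step >= burn_in:
                accepted_post += 1
        rows.append((step, ids[cur], ids[prop], bool(accept), logl[cur]))
    if accepted_post == 0:
        warnings.warn(
            "chain never accepted a move after burn-in; posterior reduces to "
            f"the single member id={ids[cur]} "
            f"(logL range {logl.min():.1f}..{logl.max():.1f})", stacklevel=2)
    trace = pd.DataFrame(rows, columns=["step", "current_id", "proposed_id",
                                        "accepted", "log_likelihood"])
    post = trace.iloc[burn_in:]
    visited = np.unique(post["current_id"].to_numpy())
    vis_logl = {i: logl[ids.index(int(i))] for i in visited}
    ranked = sorted(visited, key=lambda i: (-vis_logl[i], i))
    n_keep = max(1, math.ceil(keep_fraction * len(ranked)))
    selected = sorted(int(i) for i in ranked[:n_keep])
    sel_values = ensemble.subset(selected).values
    intervals = _trait_intervals(sel_values, selected)
    return SelectionResult(selected, trace, intervals, settings)
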