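"""Trait assemblages: sampled vectors of plant hydraulic/physiological parameters.

A trait assemblage is treated as a candidate community-mean strategy for the
stand; the calibration module samples, filters and selects assemblages, and the
simulator consumes them one (or a batch) at a time.
"""
from __future__ import annotations

import dataclasses
import json
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclasses.dataclass(frozen=True)
class TraitAssemblage:
    """One vector of plant hydraulic and physiological traits.

    Units and sign conventions follow field practice: water potentials are
    negative MPa, conductances positive, fractions in [0, 1].
    """

    p50_stem: float        # MPa (<0), 50% stem conductivity loss
    shape_stem: float      # unitless (>0), stem vulnerability shape
    p50_root: float        # MPa (<0), root vulnerability P50
    shape_root: float      # unitless (>0), root vulnerability shape
    p50_gs: float          # MPa (<0), leaf psi at 50% stomatal conductance
    a_gs: float            # unitless (>0), stomatal vulnerability shape
    g0: float              # mol m-2 s-1 (>=0), minimum/cuticular conductance
    g1: float              # unitless (>0), stomatal slope
    theta_sat_stem: float  # cm3 cm-3 (0-1), stem saturated water content
    resid_frac_stem: float # unitless (0-1), stem residual water fraction
    pi0: float             # MPa (<0), osmotic potential at full turgor
    eps_bulk: float        # MPa (>0), bulk elastic modulus
    cap_frac: float        # unitless (0-0.1), capillary-stage water fraction
    kmax_plant: float      # mmol m-2 s-1 MPa-1 (>0), max whole-plant conductance per leaf area
    taper_exp: float       # unitless, xylem taper exponent for sapwood
    srl: float             # m g-1 (>0), specific root length
    sla: float             # m2 g-1 (>0), specific leaf area
    vcmax25: float         # umol m-2 s-1 (>0), max carboxylation rate at 25 C

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        def fail(msg: str) -> None:
            raise ValueError(f"invalid TraitAssemblage: {msg}")

        for name in ("p50_stem", "p50_root", "p50_gs", "pi0"):
            if not getattr(self, name) < 0:
                fail(f"{name} must be strictly negative, got {getattr(self, name)}")
        for name in ("shape_stem", "shape_root", "a_gs", "g1", "eps_bulk",
                     "kmax_plant", "srl", "sla", "vcmax25"):
            if not getattr(self, name) > 0:
                fail(f"{name} must be positive, got {getattr(self, name)}")
        if self.g0 < 0:
            fail(f"g0 must be >= 0, got {self.g0}")
        if not 0.0 < self.theta_sat_stem < 1.0:
            fail(f"theta_sat_stem must be in (0, 1), got {self.theta_sat_stem}")
        if not 0.0 <= self.resid_frac_stem < 1.0:
            fail(f"resid_frac_stem must be in [0, 1), got {self.resid_frac_stem}")
        if not 0.0 <= self.cap_frac <= 0.1:
            fail(f"cap_frac must be in [0, 0.1], got {self.cap_frac}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TraitAssemblage":
        return cls(**{f: float(d[f]) for f in TRAIT_FIELDS})

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "TraitAssemblage":
        return cls.from_dict(json.loads(s))


TRAIT_FIELDS: tuple = tuple(f.name for f in dataclasses.fields(TraitAssemblage))


class TraitEnsemble:
    """Column-wise view of a list of assemblages for vectorized simulation.

    Stores an (n, n_traits) float array plus stable integer ids so that
    calibration can refer to members independent of ordering.
    """

    def __init__(self, values: np.ndarray, ids: Sequence[int] | None = None):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[1] != len(TRAIT_FIELDS):
            raise ValueError(
                f"expected (n, {len(TRAIT_FIELDS)}) trait array, got {values.shape}")
        self.values = values
        self.ids = np.arange(len(values)) if ids is None else np.asarray(ids, dtype=int)
        if len(self.ids) != len(values):
            raise ValueError("ids length does not match values")

    @classmethod
    def from_assemblages(cls, assemblages: Iterable[TraitAssemblage],
                         ids: Sequence[int] | None = None) -> "TraitEnsemble":
        rows = [[getattr(a, f) for f in TRAIT_FIELDS] for a in assemblages]
        return cls(np.asarray(rows, dtype=float), ids=ids)

    def __len__(self) -> int:
        return len(self.values)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, TRAIT_FIELDS.index(name)]

    def member(self, i: int) -> TraitAssemblage:
        return TraitAssemblage(**dict(zip(TRAIT_FIELDS, self.values[i])))

    def subset(self, ids: Sequence[int]) -> "TraitEnsemble":
        ids = np.asarray(ids, dtype=int)
        pos = {mid: k for k, mid in enumerate(self.ids)}
        idx = np.array([pos[i] for i in ids], dtype=int)
        return TraitEnsemble(self.values[idx], ids=ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(TRAIT_FIELDS))
        df.insert(0, "assemblage_id", self.ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TraitEnsemble":
        return cls(df[list(TRAIT_FIELDS)].to_numpy(dtype=float),
                   ids=df["assemblage_id"].to_numpy(dtype=int))
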