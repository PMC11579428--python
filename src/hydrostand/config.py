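"""Simulation configuration: stand structure, soil, numerical tolerances."""
from __future__ import annotations

import dataclasses

import yaml

from .soil import SoilParams


@dataclasses.dataclass
class SimConfig:
    """Static-stand configuration for the hydrodynamics simulator.

    The stand is a single big-leaf cohort with fixed LAI and height; plant
    water storage volumes (mm per ground area) set the compartment
    capacitances together with each assemblage's pressure-volume traits.
    """

    lai: float = 5.0                 # m2 m-2, fixed leaf area index
    height_m: float = 30.0           # canopy height used for taper and gravity
    k_ext: float = 0.5               # canopy light extinction coefficient
    patm: float = 101325.0           # Pa
    soil: SoilParams = dataclasses.field(default_factory=SoilParams)

    # compartment storage scaling
    wood_volume_mm: float = 60.0     # sapwood volume as mm water-equivalent at rwc 1
    v_rhiz_mm: float = 15.0          # rhizosphere shell capacity (mm)
    v_aroot_mm: float = 2.5          # absorbing-root capacity (mm)
    v_troot_mm: float = 10.0         # transporting-root capacity (mm)
    leaf_water_per_dry_mass: float = 1.5   # g water per g leaf dry mass at saturation
    v_leaf_base_mm: float = 1.0      # twig/branch water exchanging on the leaf node
    srl_ref: float = 25.0            # m g-1, reference specific root length
    soil_interface_factor: float = 5.0  # soil->rhizosphere max conductance multiplier

    # numerics
    vulnerability_at: str = "mean"   # "mean" or "upstream" pair-potential rule
    max_frac_change: float = 0.02    # max rwc change per sub-step
    max_substeps: int = 30
    leaf_residual_tol: float = 1e-6
    rwc_clamp_margin: float = 1e-6   # keeps rwc (and psi) away from the residual pole
    psi_floor: float = -20.0         # MPa; tissues/soil shells never operate below
                                     # this, and PLC saturates far above it

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "soil" in d and isinstance(d["soil"], dict):
            d["soil"] = SoilParams(**d["soil"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
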