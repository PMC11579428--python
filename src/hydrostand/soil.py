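"""Single-layer soil bucket: Campbell retention, drainage, soil evaporation."""
from __future__ import annotations

import dataclasses

import numpy as np


@dataclasses.dataclass
class SoilParams:
    theta_sat: float = 0.5      # m3 m-3 saturated volumetric water content
    psi_sat: float = -0.002     # MPa air-entry (saturated) potential
    k_sat: float = 20.0         # mm h-1 saturated hydraulic conductivity
    b: float = 5.0              # Campbell retention exponent
    depth_m: float = 1.0        # rooting-zone depth
    theta_init_rel: float = 0.85  # initial theta / theta_sat

    @property
    def capacity_mm(self) -> float:
        return self.theta_sat * self.depth_m * 1000.0


def soil_retention(theta, theta_sat, psi_sat, k_sat, b):
    """Campbell water retention: (psi_soil MPa, k_soil mm h-1).

    psi = psi_sat * (theta/theta_sat)^(-b); k = k_sat * (theta/theta_sat)^(2b+3).
    Both are monotone in theta.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0):
        raise ValueError("theta must be positive")
    rel = np.minimum(theta / theta_sat, 1.0)
    psi = psi_sat * rel**(-b)
    k = k_sat * rel**(2.0 * b + 3.0)
    if np.ndim(psi):
        return psi, k
    return float(psi), float(k)


# Priestley-Taylor soil evaporation on the below-canopy energy fraction.
_GAMMA_KPA = 0.0665   # psychrometric constant, kPa K-1
_ALPHA_PT = 1.26
_LAMBDA_MJ = 2.45     # latent heat of vaporization, MJ kg-1
_RN_FRACTION = 0.8    # net/incident shortwave below the canopy


def soil_evaporation(swdown, tair_c, theta_rel, lai, k_ext=0.5):
    """Potential soil evaporation (mm h-1), scaled by theta/theta_sat.

    Priestley-Taylor on the shortwave energy penetrating the canopy
    (exp(-k_ext * LAI) of incident), linearly throttled by relative soil
    water content.
    """
    es_slope = (4098.0 * 0.6108 * np.exp(17.27 * tair_c / (tair_c + 237.3))
                / (tair_c + 237.3) ** 2)  # kPa K-1
    rn = max(swdown, 0.0) * np.exp(-k_ext * lai) * _RN_FRACTION  # W m-2
    rn_mj_h = rn * 3600.0 * 1e-6
    e_pot = _ALPHA_PT * es_slope / (es_slope + _GAMMA_KPA) * rn_mj_h / _LAMBDA_MJ
    return e_pot * np.clip(theta_rel, 0.0, 1.0)
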