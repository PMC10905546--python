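"""Microstructure relations: porosity, permeability, conductivity, diffusivity.

The interstitium is treated as an isotropic porous medium.  The
Kozeny–Carman relation estimates intrinsic permeability from porosity
``epsilon`` and the pore surface density ``alpha`` (pore boundary area per
bulk volume), k = eps^3 / (Q alpha^2); hydraulic conductivity is K = k/mu;
hindered diffusion scales as Deff = eps * D.  Eliminating eps between these
at fixed alpha gives K proportional to eps^3 and therefore

    Deff / Deff0 = (K / K0)^(1/3)

which lets a drug's effective diffusivity be mapped from a locally measured
hydraulic conductivity.  The 1/3 exponent is the unique value consistent
with Deff = eps*D and K ∝ eps^3, but it is configurable so the cubic
reading can be explored as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PorousMedium",
    "DiffusivityScaling",
    "kc_permeability",
    "conductivity_from_permeability",
    "effective_diffusivity_porosity",
    "effective_diffusivity_from_K",
]


@dataclass(frozen=True)
class PorousMedium:
    """Porous-medium description of the interstitium.

    epsilon : porosity, dimensionless in (0, 1)
    alpha   : pore surface area per bulk volume [1/m]
    Q       : Kozeny–Carman constant (≈5 for epsilon < 0.7)
    mu      : interstitial fluid viscosity [Pa s]
    D_free  : solute diffusion coefficient in free fluid [m^2/s]
    """

    epsilon: float
    alpha: float
    Q: float = 5.0
    mu: float = 3.5e-3
    D_free: float = 1e-9

    def __post_init__(self) -> None:
        if not 0 < self.epsilon < 1:
            raise ValueError("porosity epsilon must lie in (0, 1)")
        if self.alpha <= 0:
            raise ValueError("pore surface density alpha must be positive")
        if self.Q <= 0:
            raise ValueError("Kozeny-Carman constant Q must be positive")


@dataclass(frozen=True)
class DiffusivityScaling:
    """Baselines for mapping conductivity to effective diffusivity.

    ``Deff_ref`` is the effective diffusion coefficient at the reference
    conductivity ``K_ref``; ``exponent`` defaults to 1/3 (see module docs).
    """

    K_ref: float
    Deff_ref: float
    exponent: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if self.K_ref <= 0 or self.Deff_ref <= 0:
            raise ValueError("K_ref and Deff_ref must be positive")


def kc_permeability(medium: PorousMedium) -> float:
    """Kozeny–Carman intrinsic permeability k = eps^3 / (Q alpha^2) [m^2]."""
    return medium.epsilon**3 / (medium.Q * medium.alpha**2)


def conductivity_from_permeability(k: float, mu: float) -> float:
    """Hydraulic conductivity K = k / mu [m^2/(Pa s)]."""
    if mu <= 0:
        raise ValueError("viscosity mu must be positive")
    return k / mu


def effective_diffusivity_porosity(epsilon: float, D_free: float) -> float:
    """Porosity-hindered diffusivity Deff = eps * D [m^2/s]."""
    return epsilon * D_free


def effective_diffusivity_from_K(K, scaling: DiffusivityScaling):
    """Deff = Deff_ref * (K / K_ref)^exponent, elementwise over K.

    Raises for non-positive K (the power law is only meaningful for a
    conducting medium).
    """
    K = np.asarray(K, dtype=float)
    if np.any(K <= 0):
        raise ValueError("K must be strictly positive")
    out = scaling.Deff_ref * (K / scaling.K_ref) ** scaling.exponent
    return float(out) if out.ndim == 0 else out
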