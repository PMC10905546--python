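"""Three-region spherical tumor geometry and radial conductivity maps.

The simulated tumor is a sphere of radius ``R_t`` (default 5 mm) embedded in
normal tissue, with a necrotic core of radius ``R_n`` (default 2.5 mm), a
hypoxic shell of configurable thickness and a viable rim out to ``R_t``.
The far-field boundary where normal-tissue conditions (IFP = 0) apply sits
at ``R_domain`` (default 4 R_t).

Hydraulic conductivity varies radially through a :class:`KProfile`:

* ``homogeneous`` — a single intratumoral value, ramping smoothly to the
  normal-tissue value across ``transition_width`` beyond the tumor edge;
* ``heterogeneous`` — constant ``K_necrotic`` in the core, a monotone
  shape-preserving (PCHIP) rise from ``K2`` at the core boundary to ``K1``
  at the tumor edge, then the same smooth ramp to ``K_normal``.

K1 and K2 are anchored to conductivities measured on the superficial (S1)
and deeper (S2) slices of a resected tumor.  Evaluation is continuous (C¹)
everywhere; monotone between anchors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "TumorGeometry",
    "KProfile",
    "evaluate_K",
    "profile_from_slices",
    "homogeneous_profile",
    "REGIONS",
]

#: Region labels from the center outward.
REGIONS = ("necrotic", "hypoxic", "viable", "normal")


@dataclass(frozen=True)
class TumorGeometry:
    """Concentric three-region tumor embedded in normal tissue (meters)."""

    R_t: float = 5e-3
    R_n: float = 2.5e-3
    hypoxic_thickness: float = 2.5e-3
    R_domain: float = 20e-3

    def __post_init__(self) -> None:
        if not 0 < self.R_n:
            raise ValueError("R_n must be positive")
        if self.hypoxic_thickness < 0:
            raise ValueError("hypoxic_thickness must be non-negative")
        if self.R_n + self.hypoxic_thickness > self.R_t:
            raise ValueError("necrotic core + hypoxic shell exceed tumor radius")
        if not self.R_t < self.R_domain:
            raise ValueError("R_domain must exceed the tumor radius")

    def region_of(self, r) -> np.ndarray:
        """Region label for each radius."""
        r = np.asarray(r, dtype=float)
        out = np.full(r.shape, "normal", dtype=object)
        out[r < self.R_t] = "viable"
        out[r < self.R_n + self.hypoxic_thickness] = "hypoxic"
        out[r < self.R_n] = "necrotic"
        return out


@dataclass(frozen=True)
class KProfile:
    """Radial hydraulic-conductivity map, all values in m^2/(Pa s)."""

    K1: float  # value at the tumor edge (superficial slice S1)
    K2: float  # interior value at the necrotic boundary (slice S2)
    K_normal: float
    K_necrotic: float
    shape: str = "heterogeneous"  # or "homogeneous"
    transition_width: float = 5e-4  # tumor->normal ramp width [m]

    def __post_init__(self) -> None:
        for name in ("K1", "K2", "K_normal", "K_necrotic"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.shape not in ("homogeneous", "heterogeneous"):
            raise ValueError("shape must be 'homogeneous' or 'heterogeneous'")
        if self.transition_width <= 0:
            raise ValueError("transition_width must be positive")
        if self.shape == "homogeneous" and self.K1 != self.K2:
            raise ValueError("homogeneous profile requires K1 == K2")

    @property
    def K_tumor(self) -> float:
        """Intratumoral value of a homogeneous profile."""
        if self.shape != "homogeneous":
            raise ValueError("K_tumor is defined for homogeneous profiles only")
        return self.K1


def _anchors(profile: KProfile, geometry: TumorGeometry):
    tw = min(profile.transition_width, geometry.R_domain - geometry.R_t)
    if profile.shape == "homogeneous":
        r = [0.0, geometry.R_t, geometry.R_t + tw, geometry.R_domain]
        K = [profile.K_tumor, profile.K_tumor, profile.K_normal, profile.K_normal]
    else:
        r = [0.0, geometry.R_n]
        K = [profile.K_necrotic, profile.K_necrotic]
        if profile.K_necrotic != profile.K2:
            # blend from the core constant to K2 just outside the core
            blend = min(tw, 0.25 * (geometry.R_t - geometry.R_n))
            r.append(geometry.R_n + blend)
            K.append(profile.K2)
        r += [geometry.R_t, geometry.R_t + tw, geometry.R_domain]
        K += [profile.K1, profile.K_normal, profile.K_normal]
    # drop duplicate radii (e.g. transition_width spanning to R_domain)
    r = np.asarray(r)
    K = np.asarray(K)
    keep = np.concatenate([[True], np.diff(r) > 0])
    return r[keep], K[keep]


def evaluate_K(profile: KProfile, geometry: TumorGeometry, r) -> np.ndarray:
    """Evaluate the conductivity map at radii ``r`` (meters).

    Shape-preserving cubic interpolation through the region anchors keeps
    the map continuous and monotone between anchors; it is constant in the
    necrotic core and beyond the tumor/normal transition.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0) or np.any(r_arr > geometry.R_domain):
        raise ValueError("r outside [0, R_domain]")
    ra, Ka = _anchors(profile, geometry)
    interp = PchipInterpolator(ra, Ka, extrapolate=False)
    out = interp(r_arr)
    return float(out) if out.ndim == 0 else out


def homogeneous_profile(
    K_tumor: float,
    K_normal_factor: float = 5.0,
    K_normal: float | None = None,
    transition_width: float = 5e-4,
) -> KProfile:
    """Single intratumoral K with K_normal = factor * K_tumor by default."""
    if K_normal is None:
        K_normal = K_normal_factor * K_tumor
    return KProfile(
        K1=K_tumor,
        K2=K_tumor,
        K_normal=K_normal,
        K_necrotic=K_tumor,
        shape="homogeneous",
        transition_width=transition_width,
    )


def profile_from_slices(
    K_S1: float,
    K_S2: float,
    K_normal_factor: float = 5.0,
    K_normal: float | None = None,
    K_necrotic: float | None = None,
    transition_width: float = 5e-4,
) -> KProfile:
    """Heterogeneous map anchored to two measured slices.

    S1 is the most superficial slice, so its conductivity anchors the tumor
    edge (K1) and the S2 value anchors the interior (K2) and, by default,
    the necrotic core.  ``K_normal`` defaults to ``K_normal_factor`` times
    the tumor-edge value; pass an explicitly measured normal-tissue
    conductivity to override.
    """
    if K_S1 <= 0 or K_S2 <= 0:
        raise ValueError("slice conductivities must be positive")
    if K_normal is None:
        K_normal = K_normal_factor * K_S1
    if K_necrotic is None:
        K_necrotic = K_S2
    shape = "homogeneous" if K_S1 == K_S2 == K_necrotic else "heterogeneous"
    return KProfile(
        K1=K_S1,
        K2=K_S2,
        K_normal=K_normal,
        K_necrotic=K_necrotic,
        shape=shape,
        transition_width=transition_width,
    )
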