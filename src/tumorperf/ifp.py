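"""Steady interstitial fluid pressure and velocity in spherical symmetry.

Darcy flow through the interstitium combined with the continuity equation
gives the steady-state pressure problem

    -div( K(r) grad p ) = J_V(p) - J_L(p)

where the transvascular source follows Starling's law,

    J_V = Lp (S/V) (p_v - p - sigma (pi_v - pi_i))     [1/s]

and the lymphatic sink, active in normal tissue only,

    J_L = Lp_L (S_L/V_L) (p - p_L)                     [1/s]

Both are linear in p, so the discrete problem is a single sparse linear
solve.  The domain is a sphere of radius ``R_domain``: zero flux at the
center by symmetry, Dirichlet p = 0 (normalized far-field IFP) at the outer
boundary.  Discretization is cell-centered finite volume with harmonic
averaging of K at cell faces, which preserves flux continuity across
conductivity jumps; the scheme is discretely conservative, so the global
mass balance closes to linear-solver precision.

The interstitial fluid velocity follows from Darcy's law at cell faces,
u = -K dp/dr.  Its maximum sits at or near the tumor edge, where the
accumulated transvascular filtrate funnels into normal tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from tumorperf.geometry import KProfile, TumorGeometry, evaluate_K

__all__ = [
    "TransportParams",
    "RadialGrid",
    "RadialSolution",
    "solve_steady_ifp",
    "solve_steady_ifp_arrays",
    "mass_balance_residual",
]


@dataclass(frozen=True)
class TransportParams:
    """Vascular/lymphatic exchange constants for the Starling source terms.

    Tumor-region values (defaults in the published tumor range):

    Lp     : vascular hydraulic conductivity [m/(Pa s)]
    SV     : vascular surface area per tissue volume [1/m]
    p_v    : vascular pressure [Pa]
    sigma  : osmotic reflection coefficient [-]
    pi_v   : plasma osmotic pressure [Pa]
    pi_i   : interstitial osmotic pressure [Pa]

    Normal tissue has its own wall properties (tighter vessels, lower
    interstitial osmotic pressure) plus a lymphatic drainage term with
    conductance ``LpL * SLVL`` relative to the effective lymphatic pressure
    ``p_L``.  ``vascular_regions`` / ``lymphatic_regions`` switch the source
    and sink per region; by default the necrotic core has no functional
    vasculature and lymphatics exist only in normal tissue.
    """

    Lp: float = 2.1e-11
    SV: float = 2.0e4
    p_v: float = 2080.0
    sigma: float = 0.82
    pi_v: float = 2670.0
    pi_i: float = 1960.0
    Lp_normal: float = 2.7e-12
    SV_normal: float = 7.0e3
    sigma_normal: float = 0.91
    pi_i_normal: float = 1330.0
    LpL: float = 1.9e-11
    SLVL: float = 7.0e3
    p_L: float = 0.0
    vascular_regions: tuple[str, ...] = ("hypoxic", "viable", "normal")
    lymphatic_regions: tuple[str, ...] = ("normal",)

    def __post_init__(self) -> None:
        for name in ("Lp", "SV", "Lp_normal", "SV_normal", "LpL", "SLVL"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("sigma", "sigma_normal"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def p_e(self) -> float:
        """Effective filtration pressure p_v - sigma (pi_v - pi_i), tumor."""
        return self.p_v - self.sigma * (self.pi_v - self.pi_i)

    @property
    def p_e_normal(self) -> float:
        """Effective filtration pressure in normal tissue."""
        return self.p_v - self.sigma_normal * (self.pi_v - self.pi_i_normal)


@dataclass(frozen=True)
class RadialGrid:
    """Uniform cell-centered radial grid from the center to R_domain."""

    r_faces: np.ndarray  # n_cells + 1 face radii, first is 0
    r_centers: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        faces = np.asarray(self.r_faces, dtype=float)
        if faces[0] != 0 or not np.all(np.diff(faces) > 0):
            raise ValueError("faces must start at 0 and increase strictly")
        object.__setattr__(self, "r_faces", faces)
        object.__setattr__(self, "r_centers", 0.5 * (faces[:-1] + faces[1:]))

    @classmethod
    def uniform(cls, R_domain: float, n_cells: int) -> "RadialGrid":
        if n_cells < 4:
            raise ValueError("need at least 4 cells")
        return cls(np.linspace(0.0, R_domain, n_cells + 1))

    @property
    def n_cells(self) -> int:
        return self.r_centers.size

    @property
    def cell_volumes(self) -> np.ndarray:
        f = self.r_faces
        return 4.0 * np.pi / 3.0 * (f[1:] ** 3 - f[:-1] ** 3)

    @property
    def face_areas(self) -> np.ndarray:
        return 4.0 * np.pi * self.r_faces**2

    def check_resolves(self, geometry: TumorGeometry, min_cells: int = 5) -> None:
        """Require at least ``min_cells`` cells in every tissue region."""
        regions = geometry.region_of(self.r_centers)
        for name in ("necrotic", "hypoxic", "viable", "normal"):
            n = int(np.sum(regions == name))
            if 0 < _region_extent(geometry, name) and n < min_cells:
                raise ValueError(
                    f"grid resolves region '{name}' with only {n} cells "
                    f"(need >= {min_cells}); refine the grid"
                )


def _region_extent(geometry: TumorGeometry, name: str) -> float:
    bounds = {
        "necrotic": geometry.R_n,
        "hypoxic": geometry.hypoxic_thickness,
        "viable": geometry.R_t - geometry.R_n - geometry.hypoxic_thickness,
        "normal": geometry.R_domain - geometry.R_t,
    }
    return bounds[name]


@dataclass(frozen=True)
class RadialSolution:
    """Steady flow field on a radial grid."""

    grid: RadialGrid
    p_i: np.ndarray  # IFP at cell centers [Pa]
    u_i: np.ndarray  # IFV at cell faces [m/s], u_i[0] = 0 by symmetry
    J_V: np.ndarray  # transvascular source at cell centers [1/s]
    J_L: np.ndarray  # lymphatic sink at cell centers [1/s]
    K_cells: np.ndarray  # conductivity at cell centers [m^2/(Pa s)]
    residual: float  # normalized global mass-balance defect


def _harmonic(Ka: np.ndarray, Kb: np.ndarray) -> np.ndarray:
    return 2.0 * Ka * Kb / (Ka + Kb)


def solve_steady_ifp_arrays(
    grid: RadialGrid,
    K_cells: np.ndarray,
    a_v: np.ndarray,
    p_e_eff: np.ndarray,
    a_L: np.ndarray,
    p_L: float = 0.0,
    p_outer: float = 0.0,
) -> RadialSolution:
    """Low-level solve from per-cell coefficient arrays.

    ``a_v = Lp*S/V`` and ``a_L = LpL*SL/VL`` are per-cell exchange
    conductances [1/(Pa s)]; ``p_e_eff`` is the per-cell effective
    filtration pressure.  The source is a_v*(p_e_eff - p), the sink
    a_L*(p - p_L).
    """
    n = grid.n_cells
    K_cells = np.broadcast_to(np.asarray(K_cells, dtype=float), (n,))
    a_v = np.broadcast_to(np.asarray(a_v, dtype=float), (n,))
    a_L = np.broadcast_to(np.asarray(a_L, dtype=float), (n,))
    p_e_eff = np.broadcast_to(np.asarray(p_e_eff, dtype=float), (n,))
    V = grid.cell_volumes
    A = grid.face_areas
    rc = grid.r_centers

    # interior-face transmissibilities, harmonic K
    K_face = _harmonic(K_cells[:-1], K_cells[1:])
    T_int = A[1:-1] * K_face / np.diff(rc)  # length n-1
    # outer boundary: Dirichlet p_outer at the last face (half-cell distance)
    T_out = A[-1] * K_cells[-1] / (grid.r_faces[-1] - rc[-1])

    main = np.zeros(n)
    main[:-1] += T_int
    main[1:] += T_int
    main[-1] += T_out
    main += (a_v + a_L) * V
    lower = -T_int
    Amat = sp.diags([lower, main, lower], offsets=(-1, 0, 1), format="csc")
    b = (a_v * p_e_eff + a_L * p_L) * V
    b[-1] += T_out * p_outer

    p = spsolve(Amat, b)

    u = np.zeros(n + 1)
    u[1:-1] = -K_face * np.diff(p) / np.diff(rc)
    u[-1] = -K_cells[-1] * (p_outer - p[-1]) / (grid.r_faces[-1] - rc[-1])

    J_V = a_v * (p_e_eff - p)
    J_L = a_L * (p - p_L)

    sol = RadialSolution(
        grid=grid, p_i=p, u_i=u, J_V=J_V, J_L=J_L,
        K_cells=np.array(K_cells), residual=np.nan,
    )
    object.__setattr__(sol, "residual", mass_balance_residual(sol))
    if not np.all(np.isfinite(p)):
        raise RuntimeError(
            "IFP solve produced non-finite pressures; check that the grid "
            "and transport coefficients are well posed"
        )
    return sol


def solve_steady_ifp(
    grid: RadialGrid,
    profile: KProfile,
    geometry: TumorGeometry,
    params: TransportParams,
) -> RadialSolution:
    """Steady IFP/IFV for a conductivity map on the tumor geometry.

    Per-region Starling coefficients are assembled from ``params`` (tumor
    wall properties inside the tumor, normal-tissue properties outside,
    sources and sinks switched per ``params.vascular_regions`` and
    ``params.lymphatic_regions``), then the linear finite-volume problem is
    solved directly.
    """
    grid.check_resolves(geometry)
    rc = grid.r_centers
    if grid.r_faces[-1] != geometry.R_domain:
        raise ValueError("grid must span exactly [0, R_domain]")
    K_cells = evaluate_K(profile, geometry, rc)
    regions = geometry.region_of(rc)
    is_normal = regions == "normal"

    a_v = np.where(is_normal, params.Lp_normal * params.SV_normal,
                   params.Lp * params.SV)
    p_e = np.where(is_normal, params.p_e_normal, params.p_e)
    vascular_on = np.isin(regions, params.vascular_regions)
    a_v = np.where(vascular_on, a_v, 0.0)

    lymph_on = np.isin(regions, params.lymphatic_regions)
    a_L = np.where(lymph_on, params.LpL * params.SLVL, 0.0)

    return solve_steady_ifp_arrays(grid, K_cells, a_v, p_e, a_L, params.p_L)


def mass_balance_residual(sol: RadialSolution) -> float:
    """Normalized conservation defect |boundary outflow - net source|.

    The outer-face volumetric outflow u*A must balance the volume integral
    of J_V - J_L; the defect is normalized by the total source magnitude
    (or reported absolutely when there is no source at all, in which case
    it is exactly zero for the direct solve).
    """
    grid = sol.grid
    outflow = sol.u_i[-1] * grid.face_areas[-1]
    net_source = np.sum((sol.J_V - sol.J_L) * grid.cell_volumes)
    scale = np.sum(np.abs(sol.J_V) * grid.cell_volumes)
    defect = abs(outflow - net_source)
    return float(defect / scale) if scale > 0 else float(defect)
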