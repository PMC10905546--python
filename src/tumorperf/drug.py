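"""Transient interstitial drug transport on a solved radial flow field.

The interstitial concentration C(r, t) of a drug delivered at the tumor
surface (intraperitoneal bath contact) obeys an advection–diffusion
equation with transvascular and lymphatic exchange:

    dC/dt = div( Deff grad C ) - div( u C ) + phi_V - phi_L

* ``u`` is the steady interstitial fluid velocity from the IFP solve;
* ``Deff`` is evaluated cell-wise from the local hydraulic conductivity
  through the microstructure power law Deff = Deff0 (K/K0)^(1/3);
* transvascular exchange couples convection and diffusion across the
  vessel wall through the transmural Peclet number
  Pe = J_V (1 - sigma_d) / (Ld S/V):

      phi_V = Ld (S/V) (c_p - C) Pe/(e^Pe - 1) + J_V (1 - sigma_d) c_p

  (the factor Pe/(e^Pe-1) -> 1 as Pe -> 0); with a negligible plasma
  concentration (c_p = 0, short therapeutic window) this is a pure sink;
* lymphatic uptake is phi_L = J_L C in normal tissue.

Note the conservative form div(Deff grad C): the spatially varying
diffusivity demands it even though the constant-coefficient Laplacian form
is common shorthand.  Discretization is finite volume with first-order
upwinded advection and a fully implicit (backward Euler) step; the
resulting M-matrix guarantees positivity and the 0 <= C <= C_boundary
maximum principle without a CFL restriction.  The boundary drug
concentration is a Dirichlet value pinned at the cell containing the tumor
edge, acting on both sides; C = 0 at the far-field boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from tumorperf.geometry import KProfile, TumorGeometry
from tumorperf.ifp import RadialGrid, RadialSolution, TransportParams
from tumorperf.microstructure import DiffusivityScaling, effective_diffusivity_from_K

__all__ = [
    "DrugParams",
    "ConcentrationField",
    "peclet_field",
    "peclet_factor",
    "vascular_exchange",
    "lymphatic_uptake",
    "simulate_drug",
]


@dataclass(frozen=True)
class DrugParams:
    """Drug-specific transport constants.

    Ld        : vascular wall permeability for the drug [m/s]
    sigma_d   : solvent-drag reflection coefficient [-]
    c_p       : plasma drug concentration [mol/m^3] (0 for a short window)
    C_boundary: prescribed concentration at the tumor edge [mol/m^3]
    duration  : simulated administration time [s]
    dt        : implicit time step [s]
    Deff_ref  : effective diffusivity at the reference conductivity [m^2/s]
    K_ref     : reference conductivity for the Deff power law; None means
                "use the profile's tumor-edge value"
    exponent  : Deff–K power-law exponent (1/3 by default)
    threshold_fraction : C/C_boundary level defining the penetration front
    """

    Ld: float = 1e-7
    sigma_d: float = 0.1
    c_p: float = 0.0
    C_boundary: float = 0.17
    duration: float = 3600.0
    dt: float = 5.0
    Deff_ref: float = 3e-10
    K_ref: float | None = None
    exponent: float = 1.0 / 3.0
    threshold_fraction: float = 0.01

    def __post_init__(self) -> None:
        if not 0 <= self.sigma_d <= 1:
            raise ValueError("sigma_d must lie in [0, 1]")
        if self.duration <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be positive")
        if self.Ld < 0:
            raise ValueError("Ld must be non-negative")
        if not 0 < self.threshold_fraction < 1:
            raise ValueError("threshold_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class ConcentrationField:
    """Space–time concentration field plus penetration summary."""

    grid: RadialGrid
    times: np.ndarray  # saved snapshot times [s]
    C: np.ndarray  # (len(times), n_cells) [mol/m^3]
    edge_index: int  # cell pinned to C_boundary
    budget_closure: float  # relative defect of the discrete mass budget
    penetration_depth: float  # [m] at final time, threshold-crossing extent

    def penetration_extent(
        self, threshold: float, R_t: float
    ) -> float:
        """Largest distance from the tumor edge where C >= threshold."""
        Cf = self.C[-1]
        hit = Cf >= threshold
        if not np.any(hit):
            return 0.0
        return float(np.max(np.abs(self.grid.r_centers[hit] - R_t)))


def peclet_factor(Pe) -> np.ndarray:
    """Pe / (exp(Pe) - 1) with the removable singularity at Pe = 0."""
    Pe = np.asarray(Pe, dtype=float)
    small = np.abs(Pe) < 1e-8
    safe = np.where(small, 1.0, Pe)
    out = np.where(small, 1.0 - Pe / 2.0, safe / np.expm1(safe))
    return float(out) if out.ndim == 0 else out


def peclet_field(J_V, params: DrugParams, SV) -> np.ndarray:
    """Transmural Peclet number Pe = J_V (1 - sigma_d) / (Ld S/V)."""
    J_V = np.asarray(J_V, dtype=float)
    LdSV = params.Ld * np.asarray(SV, dtype=float)
    if np.any(LdSV <= 0):
        raise ValueError("Ld * S/V must be positive to define Pe")
    out = J_V * (1.0 - params.sigma_d) / LdSV
    return float(out) if out.ndim == 0 else out


def vascular_exchange(C, c_p, Pe, params: DrugParams, SV, J_V) -> np.ndarray:
    """Transvascular drug exchange rate phi_V [mol/(m^3 s)]."""
    C = np.asarray(C, dtype=float)
    Pe = np.asarray(Pe, dtype=float)
    LdSV = params.Ld * np.asarray(SV, dtype=float)
    out = LdSV * (c_p - C) * peclet_factor(Pe) + np.asarray(J_V) * (
        1.0 - params.sigma_d
    ) * c_p
    return float(out) if out.ndim == 0 else out


def lymphatic_uptake(C, J_L) -> np.ndarray:
    """Lymphatic drug clearance phi_L = J_L C [mol/(m^3 s)]."""
    out = np.asarray(J_L, dtype=float) * np.asarray(C, dtype=float)
    return float(out) if out.ndim == 0 else out


def _deff_cells(
    K_cells: np.ndarray, profile: KProfile, params: DrugParams
) -> np.ndarray:
    K_ref = params.K_ref if params.K_ref is not None else profile.K1
    scaling = DiffusivityScaling(
        K_ref=K_ref, Deff_ref=params.Deff_ref, exponent=params.exponent
    )
    return effective_diffusivity_from_K(K_cells, scaling)


def simulate_drug(
    flow: RadialSolution,
    profile: KProfile,
    params: DrugParams,
    grid: RadialGrid | None = None,
    geometry: TumorGeometry | None = None,
    transport: TransportParams | None = None,
    n_snapshots: int = 20,
) -> ConcentrationField:
    """Advance the drug concentration on the solved steady flow field.

    ``flow`` must come from :func:`tumorperf.ifp.solve_steady_ifp` on the
    same grid.  ``geometry`` defaults to the standard three-region tumor;
    ``transport`` supplies the vascular surface density per region for the
    transmural sink (defaults match the flow solver defaults).
    """
    grid = grid or flow.grid
    if grid.n_cells != flow.grid.n_cells or not np.allclose(
        grid.r_faces, flow.grid.r_faces
    ):
        raise ValueError("flow must be solved on the same grid")
    geometry = geometry or TumorGeometry(R_domain=float(grid.r_faces[-1]))
    transport = transport or TransportParams()

    n = grid.n_cells
    rc = grid.r_centers
    V = grid.cell_volumes
    A = grid.face_areas
    regions = geometry.region_of(rc)
    is_normal = regions == "normal"
    vascular_on = np.isin(regions, transport.vascular_regions)

    Deff = _deff_cells(flow.K_cells, profile, params)

    # --- transvascular sink coefficients (c_p = 0 keeps them pure sinks) ---
    SV_cells = np.where(is_normal, transport.SV_normal, transport.SV)
    Pe = np.zeros(n)
    LdSV = params.Ld * SV_cells
    active = vascular_on & (LdSV > 0)
    Pe[active] = flow.J_V[active] * (1.0 - params.sigma_d) / LdSV[active]
    sink = np.zeros(n)  # [1/s]
    sink[active] = LdSV[active] * peclet_factor(Pe[active])
    sink += np.maximum(flow.J_L, 0.0)  # lymphatic clearance
    source = np.zeros(n)  # [mol/(m^3 s)], non-zero only if c_p > 0
    source[active] = (
        LdSV[active] * peclet_factor(Pe[active])
        + flow.J_V[active] * (1.0 - params.sigma_d)
    ) * params.c_p

    # --- transport operator: diffusion (harmonic Deff) + upwind advection ---
    D_face = 2.0 * Deff[:-1] * Deff[1:] / (Deff[:-1] + Deff[1:])
    TD = A[1:-1] * D_face / np.diff(rc)  # interior faces
    TD_out = A[-1] * Deff[-1] / (grid.r_faces[-1] - rc[-1])  # C=0 outside

    Q = flow.u_i * A  # volumetric flow across faces [m^3/s]
    Qp = np.maximum(Q[1:-1], 0.0)  # upwind from the inner cell
    Qm = np.minimum(Q[1:-1], 0.0)  # upwind from the outer cell

    main = np.zeros(n)
    main[:-1] += TD + Qp
    main[1:] += TD - Qm
    main[-1] += TD_out + max(Q[-1], 0.0)
    lower = -TD - Qp  # coefficient of C_i in row i+1
    upper = -TD + Qm  # coefficient of C_{i+1} in row i
    T = sp.diags([lower, main, upper], offsets=(-1, 0, 1), format="lil")

    edge_index = int(np.argmin(np.abs(rc - geometry.R_t)))

    S = sp.diags(sink * V, format="csc")
    M = sp.diags(V / _actual_dt(params), format="csc")

    L = (M + T.tocsc() + S).tolil()
    # Dirichlet row for the tumor-edge cell
    L.rows[edge_index] = [edge_index]
    L.data[edge_index] = [1.0]
    L = L.tocsc()
    lu = splu(L)

    dt = _actual_dt(params)
    n_steps = int(round(params.duration / dt))
    save_every = max(1, n_steps // max(1, n_snapshots))

    C = np.zeros(n)
    C[edge_index] = params.C_boundary
    times = [0.0]
    snapshots = [C.copy()]

    T_csr = T.tocsr()
    influx_total = 0.0
    clearance_total = 0.0
    free = np.ones(n, dtype=bool)
    free[edge_index] = False
    mass0 = float(np.sum(C[free] * V[free]))

    for step in range(1, n_steps + 1):
        rhs = V / dt * C + source * V
        rhs[edge_index] = params.C_boundary
        C_new = lu.solve(rhs)
        # discrete budget over the free cells at the implicit level
        transport_out = T_csr @ C_new
        influx = -float(np.sum(transport_out[free])) + float(
            np.sum(source[free] * V[free])
        )
        clearance = float(np.sum(sink[free] * C_new[free] * V[free]))
        influx_total += dt * influx
        clearance_total += dt * clearance
        C = C_new
        if step % save_every == 0 or step == n_steps:
            times.append(step * dt)
            snapshots.append(C.copy())

    if np.min(C) < -1e-10 * params.C_boundary:
        raise RuntimeError(
            f"negative concentration beyond tolerance: min C = {np.min(C):.3e}"
        )

    mass_change = float(np.sum(C[free] * V[free])) - mass0
    scale = max(abs(influx_total), abs(mass_change), 1e-300)
    closure = abs(mass_change - (influx_total - clearance_total)) / scale

    field_ = ConcentrationField(
        grid=grid,
        times=np.asarray(times),
        C=np.asarray(snapshots),
        edge_index=edge_index,
        budget_closure=closure,
        penetration_depth=np.nan,
    )
    depth = field_.penetration_extent(
        params.threshold_fraction * params.C_boundary, geometry.R_t
    )
    object.__setattr__(field_, "penetration_depth", depth)
    return field_


def _actual_dt(params: DrugParams) -> float:
    n_steps = max(1, int(round(params.duration / params.dt)))
    return params.duration / n_steps
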