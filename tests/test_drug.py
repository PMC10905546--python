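"""Drug transport: exchange terms, diffusion oracle, positivity, budgets."""

import numpy as np
import pytest
from scipy.special import erfc

from tumorperf.drug import (
    DrugParams,
    lymphatic_uptake,
    peclet_factor,
    peclet_field,
    simulate_drug,
    vascular_exchange,
)
from tumorperf.geometry import TumorGeometry, homogeneous_profile
from tumorperf.ifp import RadialGrid, RadialSolution, TransportParams, solve_steady_ifp


def still_flow(grid, K=8.8e-15):
    """Zero-velocity, source-free flow field for pure-diffusion checks."""
    n = grid.n_cells
    return RadialSolution(
        grid=grid,
        p_i=np.zeros(n),
        u_i=np.zeros(n + 1),
        J_V=np.zeros(n),
        J_L=np.zeros(n),
        K_cells=np.full(n, K),
        residual=0.0,
    )


class TestExchangeTerms:
    def test_peclet_examples(self):
        params = DrugParams(Ld=1e-8, sigma_d=0.9)
        # J_v = 1e-4 1/s, Ld*SV = 1e-4 1/s -> Pe = 0.1
        assert peclet_field(1e-4, params, 1e4) == pytest.approx(0.1)
        assert peclet_field(0.0, params, 1e4) == 0.0
        assert peclet_field(1e-4, DrugParams(Ld=1e-8, sigma_d=1.0), 1e4) == 0.0
        with pytest.raises(ValueError):
            peclet_field(1e-4, DrugParams(Ld=0.0), 1e4)

    def test_peclet_factor_removable_singularity(self):
        assert peclet_factor(0.0) == pytest.approx(1.0)
        assert peclet_factor(1e-12) == pytest.approx(1.0, abs=1e-9)
        assert peclet_factor(1.0) == pytest.approx(1 / (np.e - 1), rel=1e-12)
        # continuity across zero
        pes = np.array([-1e-6, -1e-9, 0.0, 1e-9, 1e-6])
        f = peclet_factor(pes)
        assert np.all(np.diff(f) < 0)  # strictly decreasing in Pe
        assert np.max(np.abs(f - 1)) < 1e-5

    def test_vascular_exchange_oracle(self):
        # c_p=0, C=0.1, Ld*SV=1e-4, Pe=1 -> phi_V = -1e-4*0.1/(e-1)
        params = DrugParams(Ld=1e-8)
        phi = vascular_exchange(0.1, 0.0, 1.0, params, 1e4, J_V=0.0)
        assert phi == pytest.approx(-1e-5 / (np.e - 1), rel=1e-9)
        assert phi == pytest.approx(-5.820e-6, rel=1e-3)

    def test_vascular_exchange_limits(self):
        params = DrugParams(Ld=1e-8)
        assert vascular_exchange(0.1, 0.0, 0.0, params, 1e4, 0.0) == pytest.approx(
            -1e-4 * 0.1
        )
        assert vascular_exchange(0.0, 0.0, 0.7, params, 1e4, 0.0) == 0.0

    def test_lymphatic_uptake(self):
        assert lymphatic_uptake(0.17, 1e-4) == pytest.approx(1.7e-5)
        assert lymphatic_uptake(0.0, 1e-4) == 0.0
        assert lymphatic_uptake(0.17, 0.0) == 0.0


@pytest.fixture(scope="module")
def diffusion_run():
    geom = TumorGeometry()
    grid = RadialGrid.uniform(geom.R_domain, 2000)
    flow = still_flow(grid)
    prof = homogeneous_profile(8.8e-15)
    params = DrugParams(Ld=0.0, duration=120.0, dt=0.5, K_ref=8.8e-15)
    quiet = TransportParams(Lp=0.0, Lp_normal=0.0, LpL=0.0)
    field = simulate_drug(
        flow, prof, params, grid=grid, geometry=geom, transport=quiet
    )
    return geom, grid, params, field


@pytest.fixture(scope="module")
def solved_case(geometry, transport):
    grid = RadialGrid.uniform(geometry.R_domain, 800)
    prof = homogeneous_profile(8.8e-15)
    flow = solve_steady_ifp(grid, prof, geometry, transport)
    params = DrugParams(duration=3600.0, dt=10.0, K_ref=8.8e-15)
    field = simulate_drug(
        flow, prof, params, grid=grid, geometry=geometry, transport=transport
    )
    return grid, params, field


class TestDiffusionOracle:
    def test_half_space_erfc_near_edge(self, diffusion_run):
        """Where curvature is negligible the planar erfc solution holds."""
        geom, grid, params, field = diffusion_run
        D, t = params.Deff_ref, params.duration
        a = grid.r_centers[field.edge_index]
        x = a - grid.r_centers
        mask = (x > 0) & (x < 4 * np.sqrt(D * t))
        exact = params.C_boundary * erfc(x[mask] / (2 * np.sqrt(D * t)))
        err = np.max(np.abs(field.C[-1][mask] - exact)) / params.C_boundary
        assert err < 0.02

    def test_spherical_surface_source_exact_form(self, diffusion_run):
        """w = rC maps the spherical problem onto planar diffusion exactly."""
        geom, grid, params, field = diffusion_run
        D, t = params.Deff_ref, params.duration
        rc = grid.r_centers
        a = rc[field.edge_index]
        x = a - rc
        mask = (x > 0) & (x < 4 * np.sqrt(D * t))
        exact = params.C_boundary * (a / rc[mask]) * erfc(
            x[mask] / (2 * np.sqrt(D * t))
        )
        err = np.max(np.abs(field.C[-1][mask] - exact)) / params.C_boundary
        assert err < 0.005

    def test_initial_condition(self, diffusion_run):
        _, grid, params, field = diffusion_run
        C0 = field.C[0]
        assert C0[field.edge_index] == params.C_boundary
        free = np.ones(grid.n_cells, bool)
        free[field.edge_index] = False
        assert np.all(C0[free] == 0.0)


class TestFullTransport:
    def test_maximum_principle(self, solved_case):
        _, params, field = solved_case
        assert np.min(field.C) >= -1e-12 * params.C_boundary
        assert np.max(field.C) <= params.C_boundary * (1 + 1e-9)

    def test_edge_pinned_at_boundary_concentration(self, solved_case):
        _, params, field = solved_case
        assert np.all(field.C[1:, field.edge_index] == pytest.approx(params.C_boundary))

    def test_mass_budget_closes(self, solved_case):
        _, _, field = solved_case
        assert field.budget_closure < 1e-6

    def test_penetration_depth_increases_with_K(self, geometry, transport):
        depths = []
        grid = RadialGrid.uniform(geometry.R_domain, 800)
        for K in (9.4e-16, 8.8e-15, 1.6e-14):
            prof = homogeneous_profile(K)
            flow = solve_steady_ifp(grid, prof, geometry, transport)
            params = DrugParams(duration=1800.0, dt=10.0, K_ref=8.8e-15)
            field = simulate_drug(
                flow, prof, params, grid=grid, geometry=geometry, transport=transport
            )
            depths.append(field.penetration_depth)
        assert depths[0] < depths[1] < depths[2]

    def test_grid_mismatch_rejected(self, geometry, transport):
        grid = RadialGrid.uniform(geometry.R_domain, 800)
        other = RadialGrid.uniform(geometry.R_domain, 400)
        prof = homogeneous_profile(8.8e-15)
        flow = solve_steady_ifp(grid, prof, geometry, transport)
        with pytest.raises(ValueError, match="same grid"):
            simulate_drug(flow, prof, DrugParams(), grid=other, geometry=geometry)
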