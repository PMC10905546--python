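"""Parameter study: conductivity anchors and heterogeneous maps end-to-end.

For each case — three homogeneous conductivity anchors spanning the
measured tumor range, plus heterogeneous edge/core maps with their
homogeneous equivalents — the steady interstitial flow field is solved and
the drug administered, and a tidy summary row is produced: peak and
tumor-averaged IFP, near-edge IFP, peak IFV and the radial extent of
appreciable IFV, and the drug penetration depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from tumorperf.config import RunConfig
from tumorperf.drug import ConcentrationField, DrugParams, simulate_drug
from tumorperf.geometry import KProfile, homogeneous_profile, profile_from_slices
from tumorperf.ifp import RadialGrid, RadialSolution, solve_steady_ifp

__all__ = ["CaseResult", "run_case", "run_parameter_study", "study_cases"]


@dataclass(frozen=True)
class CaseResult:
    """One simulated case with its flow, drug field and summary metrics."""

    name: str
    profile: KProfile
    flow: RadialSolution
    field: ConcentrationField
    metrics: dict


def _metrics(
    name: str,
    profile: KProfile,
    flow: RadialSolution,
    field: ConcentrationField,
    config: RunConfig,
) -> dict:
    geometry = config.geometry.build()
    grid = flow.grid
    rc = grid.r_centers
    in_tumor = rc < geometry.R_t
    V = grid.cell_volumes
    # cell nearest the tumor edge from the inside
    edge_idx = int(np.where(in_tumor)[0][-1])
    u = flow.u_i
    mask = np.abs(u) > config.study.ifv_threshold
    dr = float(np.mean(np.diff(grid.r_faces)))
    return {
        "case": name,
        "shape": profile.shape,
        "K1": profile.K1,
        "K2": profile.K2,
        "K_normal": profile.K_normal,
        "max_ifp_Pa": float(np.max(flow.p_i)),
        "edge_ifp_Pa": float(flow.p_i[edge_idx]),
        "mean_tumor_ifp_Pa": float(
            np.sum(flow.p_i[in_tumor] * V[in_tumor]) / np.sum(V[in_tumor])
        ),
        "peak_ifv_m_per_s": float(np.max(np.abs(u))),
        "peak_ifv_radius_m": float(grid.r_faces[int(np.argmax(np.abs(u)))]),
        "ifv_extent_m": float(np.count_nonzero(mask) * dr),
        "penetration_depth_m": float(field.penetration_depth),
        "mass_residual": float(flow.residual),
        "budget_closure": float(field.budget_closure),
    }


def run_case(name: str, profile: KProfile, config: RunConfig) -> CaseResult:
    """Solve flow + drug for one conductivity map under a run config."""
    geometry = config.geometry.build()
    grid = RadialGrid.uniform(geometry.R_domain, config.grid.n_cells)
    transport = config.transport.build()
    flow = solve_steady_ifp(grid, profile, geometry, transport)
    drug_params = config.drug.build()
    if drug_params.K_ref is None:
        drug_params = DrugParams(
            **{**config.drug.model_dump(), "K_ref": config.study.K_ref}
        )
    field = simulate_drug(
        flow, profile, drug_params, grid=grid, geometry=geometry,
        transport=transport,
    )
    return CaseResult(
        name=name,
        profile=profile,
        flow=flow,
        field=field,
        metrics=_metrics(name, profile, flow, field, config),
    )


def study_cases(config: RunConfig) -> list[tuple[str, KProfile]]:
    """Assemble the case list: anchors, heterogeneous maps, equivalents."""
    study = config.study
    tw = config.profile.transition_width
    cases: list[tuple[str, KProfile]] = []
    for name, K in zip(study.anchor_names, study.anchors):
        cases.append(
            (name, homogeneous_profile(K, study.K_normal_factor, transition_width=tw))
        )
    for het in study.heterogeneous:
        cases.append(
            (
                f"{het.name}_het",
                profile_from_slices(
                    het.K_S1, het.K_S2, K_normal=het.K_normal, transition_width=tw
                ),
            )
        )
        cases.append(
            (
                f"{het.name}_hom_edge",
                homogeneous_profile(
                    het.K_S1, study.K_normal_factor, transition_width=tw
                ),
            )
        )
        cases.append(
            (
                f"{het.name}_hom_core",
                homogeneous_profile(
                    het.K_S2, study.K_normal_factor, transition_width=tw
                ),
            )
        )
    return cases


def run_parameter_study(
    config: RunConfig,
) -> tuple[pd.DataFrame, dict[str, CaseResult]]:
    """Run every study case; return the tidy summary and per-case results."""
    results: dict[str, CaseResult] = {}
    rows = []
    for name, profile in study_cases(config):
        res = run_case(name, profile, config)
        results[name] = res
        rows.append(res.metrics)
    return pd.DataFrame(rows), results


def case_profile_table(res: CaseResult) -> pd.DataFrame:
    """Radial profile table (cell-centered) for one case."""
    grid = res.flow.grid
    return pd.DataFrame(
        {
            "r_m": grid.r_centers,
            "K_m2_per_Pa_s": res.flow.K_cells,
            "p_i_Pa": res.flow.p_i,
            "u_face_outer_m_per_s": res.flow.u_i[1:],
            "J_V_per_s": res.flow.J_V,
            "J_L_per_s": res.flow.J_L,
            "C_final_mol_per_m3": res.field.C[-1],
        }
    )
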