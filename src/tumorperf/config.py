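"""Structured run configuration: schema validation, defaults, provenance.

A single human-readable YAML file drives every stage.  Unknown keys are
rejected (``extra="forbid"``), so typos fail loudly before any stage runs.
Every table the pipeline writes embeds the SHA-256 of the effective
configuration and the package version as comment header lines for
provenance; re-running the same configuration reproduces the files
byte-identically.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

import tumorperf
from tumorperf.drug import DrugParams
from tumorperf.geometry import TumorGeometry
from tumorperf.ifp import TransportParams
from tumorperf.synthetic import CohortSpec

__all__ = [
    "RunConfig",
    "load_config",
    "config_hash",
    "write_table",
    "read_table",
]


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ChamberConfig(_Model):
    w: float = 1e-3
    d: float = 5.05e-3
    b: float = 1e-3
    rho: float = 998.0
    h: float = 0.16
    g: float = 9.81
    mu_if: float = 3.5e-3


class CohortConfig(_Model):
    n_samples: int = 29
    collagen_range: tuple[float, float] = (10.0, 50.0)
    k_collagen_slope: float = -0.028
    k_log10_at_zero: float = -13.52
    noise_sd: float = 0.167
    cell_mean: float = 18.0
    cell_sd: float = 6.0
    fibroblast_mean: float = 20.0
    fibroblast_sd: float = 10.0
    n_normal: int = 2
    normal_log10_k_mean: float = -12.55
    normal_log10_k_sd: float = 0.15
    normal_collagen_range: tuple[float, float] = (2.0, 8.0)

    def to_spec(self, seed: int) -> CohortSpec:
        return CohortSpec(seed=seed, **self.model_dump())


class GeometryConfig(_Model):
    R_t: float = 5e-3
    R_n: float = 2.5e-3
    hypoxic_thickness: float = 2.5e-3
    R_domain: float = 20e-3

    def build(self) -> TumorGeometry:
        return TumorGeometry(**self.model_dump())


class GridConfig(_Model):
    n_cells: int = 1000


class ProfileConfig(_Model):
    shape: str = "homogeneous"
    K_tumor: float | None = 8.8e-15  # homogeneous intratumoral value
    K1: float | None = None  # heterogeneous: tumor-edge (slice S1)
    K2: float | None = None  # heterogeneous: interior (slice S2)
    K_normal: float | None = None
    K_normal_factor: float = 5.0
    K_necrotic: float | None = None
    transition_width: float = 5e-4

    def build(self):
        from tumorperf.geometry import homogeneous_profile, profile_from_slices

        if self.shape == "homogeneous":
            if self.K_tumor is None:
                raise ValueError("homogeneous profile requires K_tumor")
            return homogeneous_profile(
                self.K_tumor,
                K_normal_factor=self.K_normal_factor,
                K_normal=self.K_normal,
                transition_width=self.transition_width,
            )
        if self.K1 is None or self.K2 is None:
            raise ValueError("heterogeneous profile requires K1 and K2")
        return profile_from_slices(
            self.K1,
            self.K2,
            K_normal_factor=self.K_normal_factor,
            K_normal=self.K_normal,
            K_necrotic=self.K_necrotic,
            transition_width=self.transition_width,
        )


class TransportConfig(_Model):
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

    def build(self) -> TransportParams:
        return TransportParams(**self.model_dump())


class DrugConfig(_Model):
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

    def build(self) -> DrugParams:
        return DrugParams(**self.model_dump())


class HeterogeneousCase(_Model):
    name: str
    K_S1: float
    K_S2: float
    K_normal: float = 2.8e-13  # measured normal-peritoneum conductivity


class StudyConfig(_Model):
    """Parameter-study cases: homogeneous anchors + heterogeneous maps.

    The anchors default to the three measured conductivities spanning the
    tumor range; heterogeneous maps pair a superficial (edge) and a deep
    (core) slice value per tumor.  ``K_ref`` fixes the diffusivity
    reference across cases so that differing K translates into differing
    effective diffusivity.
    """

    anchors: tuple[float, ...] = (9.4e-16, 8.8e-15, 1.6e-14)
    anchor_names: tuple[str, ...] = ("K_low", "K_mid", "K_high")
    K_normal_factor: float = 5.0
    heterogeneous: tuple[HeterogeneousCase, ...] = (
        HeterogeneousCase(name="T1", K_S1=6.0e-15, K_S2=3.5e-15),
        HeterogeneousCase(name="T2", K_S1=1.2e-14, K_S2=3.0e-15),
    )
    K_ref: float = 8.8e-15
    ifv_threshold: float = 1e-9  # m/s, "non-zero IFV" level


class RunConfig(_Model):
    seed: int = 0
    chamber: ChamberConfig = Field(default_factory=ChamberConfig)
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    grid: GridConfig = Field(default_factory=GridConfig)
    profile: ProfileConfig = Field(default_factory=ProfileConfig)
    transport: TransportConfig = Field(default_factory=TransportConfig)
    drug: DrugConfig = Field(default_factory=DrugConfig)
    study: StudyConfig = Field(default_factory=StudyConfig)


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML run configuration (None -> all defaults)."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)


def config_hash(config: RunConfig) -> str:
    """SHA-256 of the canonical JSON dump of the effective configuration."""
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def write_table(df: pd.DataFrame, path: str | Path, config: RunConfig | None) -> None:
    """Write a CSV with provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    digest = config_hash(config) if config is not None else "none"
    header = (
        f"# tumorperf_version={tumorperf.__version__}\n"
        f"# config_sha256={digest}\n"
    )
    path.write_text(header + df.to_csv(index=False))


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table` (skips provenance lines)."""
    return pd.read_csv(path, comment="#")
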