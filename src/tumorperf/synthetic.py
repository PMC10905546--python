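"""Synthetic inputs with known ground truth for every pipeline stage.

Two generators:

* :func:`generate_bubble_track` inverts the Darcy chamber equation: given a
  true interstitial-fluid-referenced conductivity ``K_true``, it computes
  the PBS-referenced nominal conductivity at the sampled run temperature,
  the implied bubble velocity, and emits a linear-drift bubble track with
  Gaussian position noise (frames every 10 min over 2 h, like the imaging
  protocol).  The analysis chain applied to a noiseless track recovers
  ``K_true`` exactly.

* :func:`generate_cohort` draws a tissue-sample cohort with a planted
  inverse collagen–conductivity relationship on the log10 scale,

      log10 K = a + b * collagen_pct + N(0, noise_sd),   b < 0

  and cell/fibroblast densities independent of K.  The default calibration
  is closed-form: with collagen ~ U(10, 50) % (variance 133.3), slope
  b = -0.028 spans the measured tumor envelope (1.6e-14 down to ~1.2e-15
  m^2/Pa s) across the collagen range, and noise_sd = 0.167 sets the
  population R^2 = b^2 Var(x) / (b^2 Var(x) + sd^2) to 0.79.  Optional
  normal-peritoneum samples are drawn around the measured ~2.8e-13 m^2/Pa s
  with low collagen; they sit far above the tumor trend and are excluded
  from the pooled regression by default (see ``tme_stats``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from tumorperf.exvivo import MU_IF, UssingMeasurement, pbs_viscosity

__all__ = ["CohortSpec", "generate_bubble_track", "generate_cohort", "cohort_to_frame"]

#: Tumor categories for round-robin labelling (normal peritoneum separate).
_TUMOR_LABELS = ("PC", "PM-CRC", "PM-CRC-AW", "PM-SB", "PM-OC", "OM-SB")


@dataclass(frozen=True)
class CohortSpec:
    """Ground-truth parameters of a synthetic tissue cohort.

    ``k_collagen_slope`` and ``noise_sd`` act on log10 K; ``k_log10_at_zero``
    is the intercept a.  ``n_normal`` normal-peritoneum samples are appended
    with conductivity ~ lognormal around ``normal_log10_k_mean``.
    """

    n_samples: int = 29
    collagen_range: tuple[float, float] = (10.0, 50.0)
    k_collagen_slope: float = -0.028  # log10 units per % collagen
    k_log10_at_zero: float = -13.52
    noise_sd: float = 0.167  # lognormal K noise, log10 units
    cell_mean: float = 18.0
    cell_sd: float = 6.0
    fibroblast_mean: float = 20.0
    fibroblast_sd: float = 10.0
    n_normal: int = 2
    normal_log10_k_mean: float = -12.55
    normal_log10_k_sd: float = 0.15
    normal_collagen_range: tuple[float, float] = (2.0, 8.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValueError("n_samples must be at least 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_normal < 0:
            raise ValueError("n_normal must be non-negative")


def generate_bubble_track(
    K_true: float,
    chamber: UssingMeasurement | None = None,
    noise_sd_position: float = 5e-6,
    seed: int = 0,
    temperature_C: float | None = None,
    frame_interval: float = 600.0,
    duration: float = 7200.0,
    sample_id: str = "synthetic",
) -> UssingMeasurement:
    """Linear-drift-plus-noise bubble track for a known conductivity.

    ``K_true`` is the corrected (interstitial-fluid-referenced) value the
    analysis chain should recover.  ``chamber`` supplies geometry/fluid
    constants (defaults match the packaged chamber); the run temperature is
    sampled uniformly in the 18–25 °C room-temperature window unless given.
    """
    if K_true <= 0:
        raise ValueError("K_true must be positive")
    rng = np.random.default_rng(seed)
    if temperature_C is None:
        temperature_C = float(rng.uniform(18.0, 25.0))
    proto = chamber or UssingMeasurement(
        sample_id=sample_id, times=[0.0, 1.0, 2.0], positions=[0.0, 0.0, 0.0]
    )
    mu_pbs = pbs_viscosity(temperature_C)
    K_nominal = K_true * MU_IF / mu_pbs  # un-apply the viscosity correction
    velocity = K_nominal * proto.rho * proto.g * proto.h / (
        (proto.b / proto.d) ** 2 * proto.w
    )
    times = np.arange(0.0, duration + frame_interval / 2, frame_interval)
    positions = velocity * times + rng.normal(0.0, noise_sd_position, times.size)
    return UssingMeasurement(
        sample_id=sample_id,
        times=times,
        positions=positions,
        temperature_C=temperature_C,
        w=proto.w,
        d=proto.d,
        b=proto.b,
        rho=proto.rho,
        h=proto.h,
        g=proto.g,
    )


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a tissue-sample cohort with the planted collagen–K relation.

    Returns a DataFrame with columns ``sample_id, tumor_type, K,
    collagen_pct, cell_pct, fibroblast_pct`` — the same layout the
    correlation stage reads.  Fully deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.collagen_range
    collagen = rng.uniform(lo, hi, spec.n_samples)
    log10K = (
        spec.k_log10_at_zero
        + spec.k_collagen_slope * collagen
        + rng.normal(0.0, spec.noise_sd, spec.n_samples)
    )
    cell = np.clip(
        rng.normal(spec.cell_mean, spec.cell_sd, spec.n_samples), 0.0, 100.0
    )
    fibro = np.clip(
        rng.normal(spec.fibroblast_mean, spec.fibroblast_sd, spec.n_samples),
        0.0,
        100.0,
    )
    types = [_TUMOR_LABELS[i % len(_TUMOR_LABELS)] for i in range(spec.n_samples)]
    rows = [
        {
            "sample_id": f"T{i // 2 + 1}S{i % 2 + 1}",
            "tumor_type": types[i],
            "K": 10.0 ** log10K[i],
            "collagen_pct": collagen[i],
            "cell_pct": cell[i],
            "fibroblast_pct": fibro[i],
        }
        for i in range(spec.n_samples)
    ]
    # normal peritoneum: high conductivity, sparse collagen, off-trend
    nlo, nhi = spec.normal_collagen_range
    for j in range(spec.n_normal):
        rows.append(
            {
                "sample_id": f"NP{j + 1}",
                "tumor_type": "NP",
                "K": 10.0
                ** rng.normal(spec.normal_log10_k_mean, spec.normal_log10_k_sd),
                "collagen_pct": float(rng.uniform(nlo, nhi)),
                "cell_pct": float(
                    np.clip(rng.normal(spec.cell_mean / 2, spec.cell_sd), 0, 100)
                ),
                "fibroblast_pct": float(
                    np.clip(
                        rng.normal(spec.fibroblast_mean / 2, spec.fibroblast_sd),
                        0,
                        100,
                    )
                ),
            }
        )
    return pd.DataFrame(rows)


def cohort_to_frame(spec: CohortSpec) -> pd.DataFrame:
    """Alias kept for symmetry with the CSV-writing CLI."""
    return generate_cohort(spec)
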