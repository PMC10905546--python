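"""Ex-vivo hydraulic conductivity from Ussing-chamber bubble tracking.

A tissue disc is clamped between two modified Ussing half-chambers and a
constant hydrostatic head drives buffer through it.  The resulting flow is
read off from the drift of an air bubble in a calibrated tube, imaged every
ten minutes over two hours.  Darcy's law applied to the disc gives the
nominal hydraulic conductivity

    K' = (b/d)^2 * w / (rho * g * h) * dx/dt          [m^2 / (Pa s)]

with ``w`` the tissue thickness, ``d`` the wet (exposed) tissue diameter,
``b`` the tube bore, ``rho`` the buffer density, ``h`` the head of the liquid
column and ``dx/dt`` the bubble velocity.  Because the chamber runs with PBS
at room temperature while the quantity of interest refers to interstitial
fluid at body temperature, K' is viscosity-corrected:

    K = (mu_PBS / mu_IF) * K'
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LeakSuspectWarning",
    "TemperatureRangeWarning",
    "UssingMeasurement",
    "ConductivityResult",
    "estimate_bubble_velocity",
    "nominal_conductivity",
    "pbs_viscosity",
    "viscosity_correct",
    "conductivity_from_track",
    "process_tracks",
]

#: Default chamber geometry and fluid constants.
DEFAULT_W = 1e-3  # tissue thickness [m]
DEFAULT_D = 5.05e-3  # tissue wet diameter [m] (exposed-area diameter)
DEFAULT_B = 1e-3  # bubble-tube bore [m]
DEFAULT_RHO = 998.0  # buffer density [kg/m^3]
DEFAULT_H = 0.16  # liquid column height [m]
DEFAULT_G = 9.81  # gravitational acceleration [m/s^2]

#: Interstitial-fluid viscosity at body temperature [Pa s].
MU_IF = 3.5e-3

#: Water/PBS viscosity anchors (temperature [degC], viscosity [Pa s]).
PBS_VISCOSITY_ANCHORS = ((18.0, 1.1e-3), (25.0, 8.9e-4))


class LeakSuspectWarning(UserWarning):
    """Net bubble drift toward the feeding side: suspect chamber leak."""


class TemperatureRangeWarning(UserWarning):
    """Temperature outside the calibrated room-temperature window."""


@dataclass
class UssingMeasurement:
    """One chamber run: bubble track plus geometry and fluid constants.

    ``times`` are seconds since the start of imaging (strictly increasing,
    at least three frames); ``positions`` are the bubble locations along the
    tube in meters.
    """

    sample_id: str
    times: np.ndarray
    positions: np.ndarray
    temperature_C: float = 21.5
    w: float = DEFAULT_W
    d: float = DEFAULT_D
    b: float = DEFAULT_B
    rho: float = DEFAULT_RHO
    h: float = DEFAULT_H
    g: float = DEFAULT_G

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.ndim != 1 or self.positions.ndim != 1:
            raise ValueError("times and positions must be 1-D")
        if self.times.size != self.positions.size:
            raise ValueError("times and positions must have equal length")
        if self.times.size < 3:
            raise ValueError("need at least 3 (time, position) frames")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        for name in ("w", "d", "b", "rho", "h", "g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class ConductivityResult:
    """Nominal and viscosity-corrected conductivity for one run."""

    sample_id: str
    K_nominal: float  # m^2/(Pa s), PBS-referenced
    K_corrected: float  # m^2/(Pa s), interstitial-fluid-referenced
    velocity: float  # m/s, OLS slope of the bubble track
    velocity_stderr: float  # m/s
    mu_pbs: float  # Pa s
    mu_if: float  # Pa s
    leak_suspect: bool = False


def estimate_bubble_velocity(times, positions) -> tuple[float, float]:
    """Bubble velocity as the OLS slope of position vs. time.

    Returns ``(velocity, stderr)`` in m/s.  Fitting all frames rather than a
    first/last difference uses every 10-min observation and yields a
    standard error for downstream uncertainty propagation.
    """
    times = np.asarray(times, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if times.size < 3:
        raise ValueError("need at least 3 frames to estimate a velocity")
    if not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    if times[-1] == times[0]:
        raise ValueError("zero time span")
    fit = stats.linregress(times, positions)
    return float(fit.slope), float(fit.stderr)


def nominal_conductivity(m: UssingMeasurement, velocity: float) -> float:
    """Nominal conductivity K' = (b/d)^2 * w * v / (rho g h).

    A negative velocity (bubble drifting toward the feeding side) is
    physically a back-flow and usually indicates a leak; the signed value is
    returned with a :class:`LeakSuspectWarning` rather than rejected, since
    leakage is screened separately before each run.
    """
    if m.h <= 0:
        raise ValueError("liquid column height h must be positive")
    if velocity < 0:
        warnings.warn(
            f"negative bubble velocity for sample {m.sample_id!r}: "
            "suspect chamber leak",
            LeakSuspectWarning,
            stacklevel=2,
        )
    return (m.b / m.d) ** 2 * m.w * velocity / (m.rho * m.g * m.h)


def pbs_viscosity(temperature_C: float, anchors=PBS_VISCOSITY_ANCHORS) -> float:
    """PBS (≈ water) viscosity at the run temperature, Pa s.

    Linear interpolation between the tabulated anchors (default 1.1e-3 Pa s
    at 18 °C and 8.9e-4 Pa s at 25 °C).  Outside the anchor window the line
    is extrapolated with a warning.
    """
    (t0, mu0), (t1, mu1) = anchors
    lo, hi = min(t0, t1), max(t0, t1)
    if not lo <= temperature_C <= hi:
        warnings.warn(
            f"temperature {temperature_C} °C outside [{lo}, {hi}] °C; "
            "extrapolating viscosity",
            TemperatureRangeWarning,
            stacklevel=2,
        )
    return mu0 + (mu1 - mu0) * (temperature_C - t0) / (t1 - t0)


def viscosity_correct(K_nominal: float, mu_pbs: float, mu_if: float = MU_IF) -> float:
    """Correct PBS-referenced K' to interstitial fluid: K = (mu_PBS/mu_IF) K'."""
    if mu_pbs <= 0 or mu_if <= 0:
        raise ValueError("viscosities must be strictly positive")
    return (mu_pbs / mu_if) * K_nominal


def conductivity_from_track(
    m: UssingMeasurement, mu_if: float = MU_IF
) -> ConductivityResult:
    """Full chain: bubble track -> velocity -> K' -> viscosity-corrected K."""
    velocity, stderr = estimate_bubble_velocity(m.times, m.positions)
    K_nom = nominal_conductivity(m, velocity)
    leak = velocity < 0
    mu_pbs = pbs_viscosity(m.temperature_C)
    K_corr = viscosity_correct(K_nom, mu_pbs, mu_if)
    return ConductivityResult(
        sample_id=m.sample_id,
        K_nominal=K_nom,
        K_corrected=K_corr,
        velocity=velocity,
        velocity_stderr=stderr,
        mu_pbs=mu_pbs,
        mu_if=mu_if,
        leak_suspect=leak,
    )


def process_tracks(tracks: pd.DataFrame, chamber: dict | None = None) -> pd.DataFrame:
    """Reduce a long-format track table to one conductivity row per sample.

    ``tracks`` needs columns ``sample_id, time_s, position_m`` and optionally
    ``temperature_C`` (constant per sample).  ``chamber`` overrides the
    default geometry/fluid constants (keys w, d, b, rho, h, g, mu_if).
    """
    required = {"sample_id", "time_s", "position_m"}
    missing = required - set(tracks.columns)
    if missing:
        raise ValueError(f"track table missing columns: {sorted(missing)}")
    chamber = dict(chamber or {})
    mu_if = chamber.pop("mu_if", MU_IF)
    rows = []
    for sample_id, grp in tracks.groupby("sample_id", sort=True):
        grp = grp.sort_values("time_s")
        kwargs = dict(chamber)
        if "temperature_C" in grp.columns:
            kwargs["temperature_C"] = float(grp["temperature_C"].iloc[0])
        m = UssingMeasurement(
            sample_id=str(sample_id),
            times=grp["time_s"].to_numpy(),
            positions=grp["position_m"].to_numpy(),
            **kwargs,
        )
        res = conductivity_from_track(m, mu_if=mu_if)
        rows.append(
            {
                "sample_id": res.sample_id,
                "K_nominal": res.K_nominal,
                "K_corrected": res.K_corrected,
                "velocity": res.velocity,
                "velocity_stderr": res.velocity_stderr,
                "mu_pbs": res.mu_pbs,
                "mu_if": res.mu_if,
                "leak_suspect": res.leak_suspect,
            }
        )
    return pd.DataFrame(rows)
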