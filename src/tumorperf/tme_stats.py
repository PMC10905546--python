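"""Correlation analysis between hydraulic conductivity and TME composition.

Simple linear regressions relate per-sample hydraulic conductivity K to the
area densities (%) of collagen fibers, cancer cells and fibroblasts, and the
densities to one another, pooled over all tumor samples and within each
tumor type.  Because K spans orders of magnitude across samples, K enters
the regressions on a log10 scale by default (configurable).

No multiple-testing correction is applied: each pair/grouping cell is a
stand-alone simple regression, reported with signed Pearson r, |r|, R²,
the two-sided slope t-test p-value and the slope standard error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TUMOR_TYPES",
    "DENSITY_PAIRS",
    "K_PAIRS",
    "TissueSample",
    "RegressionResult",
    "fit_simple_regression",
    "correlation_table",
    "samples_to_frame",
]

#: Tumor-type labels: pancreatic primary, peritoneal metastases from
#: colorectal (peritoneum and abdominal-wall), small-bowel and ovarian
#: primaries, ovarian metastasis from small bowel, and normal peritoneum.
TUMOR_TYPES = ("PC", "PM-CRC", "PM-CRC-AW", "PM-SB", "PM-OC", "OM-SB", "NP")

#: (predictor, response) pairs among the TME densities.
DENSITY_PAIRS = (
    ("collagen_pct", "cell_pct"),
    ("collagen_pct", "fibroblast_pct"),
    ("cell_pct", "fibroblast_pct"),
)

#: (predictor, response) pairs relating densities to conductivity.
K_PAIRS = (
    ("collagen_pct", "K"),
    ("cell_pct", "K"),
    ("fibroblast_pct", "K"),
)


@dataclass(frozen=True)
class TissueSample:
    """One slice: conductivity plus TME area densities and type label."""

    sample_id: str
    tumor_type: str
    K: float  # m^2/(Pa s)
    collagen_pct: float
    cell_pct: float
    fibroblast_pct: float

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("K must be positive")
        for name in ("collagen_pct", "cell_pct", "fibroblast_pct"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must lie in [0, 100]")


@dataclass(frozen=True)
class RegressionResult:
    """Simple-linear-regression summary for one variable pair."""

    slope: float
    intercept: float
    r: float
    abs_r: float
    R2: float
    p: float
    SE: float  # standard error (of the slope by default)
    n: int


def fit_simple_regression(x, y, se_mode: str = "slope") -> RegressionResult:
    """OLS fit of y on x with Pearson r, R² and a two-sided slope t-test.

    ``se_mode`` selects what the SE field reports: ``"slope"`` (standard
    error of the slope estimate, the default) or ``"estimate"`` (residual
    standard error of the fit, with n-2 degrees of freedom).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("degenerate input: x is constant")
    fit = stats.linregress(x, y)
    if se_mode == "slope":
        se = float(fit.stderr)
    elif se_mode == "estimate":
        resid = y - (fit.intercept + fit.slope * x)
        se = float(np.sqrt(np.sum(resid**2) / (x.size - 2)))
    else:
        raise ValueError("se_mode must be 'slope' or 'estimate'")
    r = float(fit.rvalue)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=r,
        abs_r=abs(r),
        R2=r * r,
        p=float(fit.pvalue),
        SE=se,
        n=int(x.size),
    )


def samples_to_frame(samples: Iterable[TissueSample]) -> pd.DataFrame:
    """Tabulate TissueSample records into the column layout the stats use."""
    rows = [
        {
            "sample_id": s.sample_id,
            "tumor_type": s.tumor_type,
            "K": s.K,
            "collagen_pct": s.collagen_pct,
            "cell_pct": s.cell_pct,
            "fibroblast_pct": s.fibroblast_pct,
        }
        for s in samples
    ]
    if not rows:
        raise ValueError("empty sample list")
    return pd.DataFrame(rows)


def correlation_table(
    samples,
    groupings: Sequence[str] | None = None,
    log_K: bool = True,
    include_normal: bool = False,
    se_mode: str = "slope",
) -> pd.DataFrame:
    """Pair × grouping regression table over a tissue-sample cohort.

    ``samples`` is a DataFrame with columns ``sample_id, tumor_type, K,
    collagen_pct, cell_pct, fibroblast_pct`` (or an iterable of
    :class:`TissueSample`).  For every variable pair and every grouping
    ("All" plus each tumor type present, unless ``groupings`` restricts
    them) one row is emitted; groups with fewer than 3 samples or a constant
    predictor appear with a ``status`` reason instead of statistics.

    With ``log_K=True`` (default) conductivity enters as log10(K).  Normal
    peritoneum ("NP") rows are excluded from the pooled "All" group unless
    ``include_normal`` is set; per-type groups are untouched.
    """
    if not isinstance(samples, pd.DataFrame):
        samples = samples_to_frame(samples)
    if samples.empty:
        raise ValueError("empty sample table")
    df = samples.copy()
    k_col = "K"
    if log_K:
        df["log10_K"] = np.log10(df["K"])
        k_col = "log10_K"

    present_types = [t for t in TUMOR_TYPES if t in set(df["tumor_type"])]
    extra_types = sorted(set(df["tumor_type"]) - set(TUMOR_TYPES))
    if groupings is None:
        groupings = ["All", *present_types, *extra_types]

    pairs = list(DENSITY_PAIRS) + [
        (x, k_col if y == "K" else y) for x, y in K_PAIRS
    ]

    rows = []
    for group in groupings:
        if group == "All":
            sub = df if include_normal else df[df["tumor_type"] != "NP"]
        else:
            sub = df[df["tumor_type"] == group]
        for x_col, y_col in pairs:
            pair_name = f"{x_col} vs {y_col}"
            row = {"pair": pair_name, "group": group, "n": int(len(sub))}
            if len(sub) < 3:
                row.update(status="too_few_samples")
            elif np.ptp(sub[x_col].to_numpy(dtype=float)) == 0:
                row.update(status="constant_predictor")
            else:
                res = fit_simple_regression(
                    sub[x_col], sub[y_col], se_mode=se_mode
                )
                row.update(
                    status="ok",
                    r=res.r,
                    abs_r=res.abs_r,
                    R2=res.R2,
                    p=res.p,
                    SE=res.SE,
                    intercept=res.intercept,
                    slope=res.slope,
                )
            rows.append(row)
    cols = [
        "pair", "group", "n", "status",
        "r", "abs_r", "R2", "p", "SE", "intercept", "slope",
    ]
    return pd.DataFrame(rows).reindex(columns=cols)
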