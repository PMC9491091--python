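"""ROI-DVR vs cognition regressions with outlier screening and Bonferroni-9.

Each of the nine assessments (CAM, five MoCA subscores, IQCODE-SF, GDS, NPI)
is regressed on the mean DVR of the highest-overlap region.  Before each
regression, observations lying more than 3 SD from the full-sample mean of
either variable are removed in a single pass.  Raw two-sided p-values come
from the t distribution with n-2 df; the Bonferroni divisor is fixed at 9
(the size of the battery) regardless of how many assessments have data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .imaging_io import ASSESSMENTS, Cohort

__all__ = [
    "RegressionResult",
    "screen_outliers",
    "simple_regression",
    "adjusted_r2",
    "run_assessment_battery",
]

N_ASSESSMENTS = 9  # fixed Bonferroni divisor


@dataclass(frozen=True)
class RegressionResult:
    assessment: str
    n_used: int
    slope: float
    intercept: float
    pearson_r: float
    r2: float
    adjusted_r2: float
    p_raw: float
    p_bonferroni: float
    outliers_removed: tuple = field(default_factory=tuple)


def screen_outliers(x: np.ndarray, y: np.ndarray, k: float = 3.0) -> np.ndarray:
    """Indices kept after removing points > k SD from either variable's mean.

    Means and SDs are taken from the full sample and the screen is a single
    pass (no re-screening after removal).  k = inf is the identity.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise ValueError("need >= 4 paired observations")
    keep = np.ones(x.size, dtype=bool)
    if np.isfinite(k):
        for v in (x, y):
            sd = v.std(ddof=0)
            if sd > 0:
                keep &= np.abs(v - v.mean()) <= k * sd
    if not keep.any():
        raise ValueError("outlier screen removed all points")
    return np.nonzero(keep)[0]


def adjusted_r2(r: float, n: int) -> float:
    """Adjusted R-squared for a single-predictor OLS: 1 - (1-r^2)(n-1)/(n-2)."""
    if n < 3:
        raise ValueError("need n >= 3")
    return 1.0 - (1.0 - r * r) * (n - 1) / (n - 2)


def simple_regression(x: np.ndarray, y: np.ndarray,
                      assessment: str = "", outliers_removed: tuple = ()
                      ) -> RegressionResult:
    """OLS of y on x with Pearson r, adjusted R-squared and two-sided p.

    x is the ROI mean DVR, y the assessment score.  Requires n >= 4 and
    non-zero variance in x.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n < 4:
        raise ValueError(f"insufficient n = {n} (need >= 4)")
    if x.std() == 0:
        raise ValueError("zero variance in x")
    fit = stats.linregress(x, y)
    r = float(fit.rvalue)
    p = float(fit.pvalue)
    return RegressionResult(
        assessment=assessment,
        n_used=int(n),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=r,
        r2=r * r,
        adjusted_r2=adjusted_r2(r, n),
        p_raw=p,
        p_bonferroni=min(1.0, N_ASSESSMENTS * p),
        outliers_removed=tuple(outliers_removed),
    )


def run_assessment_battery(cohort: Cohort, roi_dvr_by_subject: dict[str, float],
                           outlier_k: float = 3.0
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the nine-assessment regression battery against ROI mean DVR.

    Uses QC-passing subjects with a defined ROI DVR; each assessment is
    pairwise-complete.  Assessments with fewer than 4 usable pairs are
    reported as skipped.  Returns (results table, diagnostics table); the
    diagnostics carry predicted values and standardized residuals per
    subject and assessment.
    """
    table = cohort.qc_passed()
    if table.columns.duplicated().any():
        dup = table.columns[table.columns.duplicated()].tolist()
        raise ValueError(f"duplicate assessment columns: {dup}")
    table = table[table["subject_id"].isin(roi_dvr_by_subject)]
    dvr = table["subject_id"].map(roi_dvr_by_subject).to_numpy(float)

    rows, diag_rows = [], []
    for a in ASSESSMENTS:
        y_all = table[a].to_numpy(float)
        ok = np.isfinite(dvr) & np.isfinite(y_all)
        ids = table["subject_id"].to_numpy()[ok]
        x = dvr[ok]
        y = y_all[ok]
        if x.size < 4:
            rows.append({"assessment": a, "skipped": f"only {x.size} usable pairs"})
            continue
        kept = screen_outliers(x, y, k=outlier_k)
        removed = tuple(np.delete(ids, kept))
        if kept.size < 4 or x[kept].std() == 0:
            rows.append({"assessment": a,
                         "skipped": "insufficient data after outlier screen"})
            continue
        res = simple_regression(x[kept], y[kept], assessment=a,
                                outliers_removed=removed)
        rows.append({
            "assessment": a, "n_used": res.n_used, "slope": res.slope,
            "intercept": res.intercept, "pearson_r": res.pearson_r,
            "r2": res.r2, "adjusted_r2": res.adjusted_r2, "p_raw": res.p_raw,
            "p_bonferroni": res.p_bonferroni,
            "outliers_removed": ";".join(map(str, removed)), "skipped": "",
        })
        pred = res.intercept + res.slope * x[kept]
        resid = y[kept] - pred
        sd = resid.std(ddof=2) if kept.size > 2 else np.nan
        for sid, p_i, r_i in zip(ids[kept], pred, resid):
            diag_rows.append({
                "subject_id": sid, "assessment": a, "predicted": p_i,
                "residual": r_i,
                "std_residual": r_i / sd if sd and sd > 0 else np.nan,
            })
    results = pd.DataFrame(rows)
    if "skipped" not in results.columns:
        results["skipped"] = ""
    return results, pd.DataFrame(diag_rows)
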