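"""Logan reference-region graphical analysis.

The Logan plot linearizes reversible-tracer kinetics: with target TAC C_T(t)
and reference TAC C_R(t), the points

    y_i = int_0^{t_i} C_T / C_T(t_i)
    x_i = (int_0^{t_i} C_R + C_R(t_i)/k2') / C_T(t_i)

become linear for t_i beyond an equilibration time t*, and the slope is the
distribution volume ratio DVR = 1 + BP.  The k2' term is omitted by default
(classic simplified reference formulation); it can be supplied in 1/min.

Conventions (documented, self-consistent): cumulative integrals are evaluated
at frame END times and are exact for frame-averaged data (sum of
value*duration); instantaneous values are the frame averages themselves;
frames enter the fit when their MID time is >= t*.  Times inside the fit are
in minutes, so the intercept is in minutes; the slope is dimensionless either
way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .imaging_io import DynamicImage, FrameSchedule, LabelAtlas, check_same_grid

logger = logging.getLogger("neuropet")

__all__ = [
    "TimeActivityCurve",
    "LoganFit",
    "DVRMap",
    "cumulative_integral",
    "logan_fit",
    "dvr_map",
    "auto_tstar",
]


@dataclass
class TimeActivityCurve:
    """Frame-averaged activity values tied to a frame schedule."""

    values: np.ndarray
    schedule: FrameSchedule

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or self.values.size != self.schedule.n_frames:
            raise ValueError(
                f"TAC length {self.values.size} != frame count {self.schedule.n_frames}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TAC contains non-finite values")


@dataclass(frozen=True)
class LoganFit:
    """Result of one Logan fit: slope (DVR), intercept (min), fit window."""

    dvr: float
    intercept: float
    tstar: float
    n_points: int
    r2: float


@dataclass
class DVRMap:
    """Voxelwise DVR volume (NaN where undefined) plus fit provenance."""

    data: np.ndarray
    affine: np.ndarray
    tstar: float
    reference_label: int
    k2prime: float | None = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def cumulative_integral(tac: TimeActivityCurve) -> np.ndarray:
    """Cumulative integral of a frame-averaged TAC at frame end times.

    Exact for the piecewise-constant (frame-averaged) representation:
    value at frame i is sum_{j<=i} values[j] * duration[j], in
    activity * seconds.  Non-decreasing whenever the TAC is non-negative.
    """
    return np.cumsum(tac.values * tac.schedule.duration)


def _fit_window(schedule: FrameSchedule, tstar_min: float) -> np.ndarray:
    sel = schedule.mid / 60.0 >= tstar_min
    if not sel.any():
        raise ValueError(f"no frames at or beyond t* = {tstar_min} min")
    return sel


def _logan_xy(
    target_vals: np.ndarray,
    reference: TimeActivityCurve,
    sel: np.ndarray,
    k2prime: float | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Logan coordinates for one or many targets (last axis = frames)."""
    sched = reference.schedule
    dur_min = sched.duration / 60.0
    int_ref = np.cumsum(reference.values * dur_min)  # activity*min
    int_tgt = np.cumsum(target_vals * dur_min, axis=-1)
    num_x = int_ref.copy()
    if k2prime is not None:
        if k2prime <= 0:
            raise ValueError("k2prime must be positive (1/min)")
        num_x = num_x + reference.values / k2prime
    ct = target_vals[..., sel]
    y = int_tgt[..., sel] / ct
    x = num_x[sel] / ct
    return x, y


def logan_fit(
    target: TimeActivityCurve,
    reference: TimeActivityCurve,
    tstar: float = 30.0,
    k2prime: float | None = None,
) -> LoganFit:
    """Fit the Logan plot of ``target`` against ``reference``.

    Parameters
    ----------
    tstar : float
        Linearization time in minutes; frames with mid-time >= t* enter the
        ordinary-least-squares fit.
    k2prime : float, optional
        Reference-region efflux constant (1/min).  When given, the Logan
        abscissa includes the C_R(t)/k2' correction term.

    Raises
    ------
    ValueError
        If fewer than 3 frames lie at or beyond t*, or the target is not
        strictly positive inside the fit window.
    """
    if target.schedule is not reference.schedule and not (
        np.array_equal(target.schedule.start, reference.schedule.start)
        and np.array_equal(target.schedule.duration, reference.schedule.duration)
    ):
        raise ValueError("target and reference must share a frame schedule")
    sel = _fit_window(target.schedule, tstar)
    if sel.sum() < 3:
        raise ValueError(f"fewer than 3 frames at or beyond t* = {tstar} min")
    if np.any(target.values[sel] <= 0):
        raise ValueError("non-positive target activity inside the fit window")
    x, y = _logan_xy(target.values, reference, sel, k2prime)
    slope, intercept, r2 = _ols_line(x, y)
    return LoganFit(
        dvr=float(slope),
        intercept=float(intercept),
        tstar=float(tstar),
        n_points=int(sel.sum()),
        r2=float(r2),
    )


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares line fit over the last axis; returns (slope, intercept, r2).

    Broadcasts over leading axes so the voxelwise map is a single pass.
    """
    xm = x.mean(axis=-1, keepdims=True)
    ym = y.mean(axis=-1, keepdims=True)
    dx = x - xm
    dy = y - ym
    sxx = np.sum(dx * dx, axis=-1)
    sxy = np.sum(dx * dy, axis=-1)
    syy = np.sum(dy * dy, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
        r2 = np.where(syy > 0, sxy * sxy / (sxx * syy), 1.0)
    intercept = (ym - slope[..., None] * xm)[..., 0]
    return slope, intercept, r2


def auto_tstar(
    target: TimeActivityCurve,
    reference: TimeActivityCurve,
    candidates: tuple[float, ...] = (10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0),
    max_rel_residual: float = 0.10,
    k2prime: float | None = None,
) -> float:
    """Earliest candidate t* whose Logan fit has max |residual|/|y| <= 10%.

    Falls back to the latest candidate with >= 3 frames if none qualifies.
    """
    last_valid = None
    for t in candidates:
        try:
            sel = _fit_window(target.schedule, t)
        except ValueError:
            break
        if sel.sum() < 3:
            break
        last_valid = t
        x, y = _logan_xy(target.values, reference, sel, k2prime)
        slope, intercept, _ = _ols_line(x, y)
        resid = y - (slope * x + intercept)
        if np.max(np.abs(resid) / np.maximum(np.abs(y), 1e-12)) <= max_rel_residual:
            return t
    if last_valid is None:
        raise ValueError("no candidate t* leaves >= 3 frames")
    return last_valid


def dvr_map(
    image: DynamicImage,
    atlas: LabelAtlas,
    tstar: float = 30.0,
    k2prime: float | None = None,
) -> DVRMap:
    """Voxelwise Logan DVR map inside the union of atlas role regions.

    The reference TAC is the mean TAC over the reference-region voxels.
    Voxels with any non-positive activity inside the fit window are marked
    NaN (undefined) rather than raising, as are voxels outside the analysis
    mask.
    """
    check_same_grid(image, atlas)
    ref_mask = atlas.role_mask("reference_region")
    if not ref_mask.any():
        raise ValueError("empty reference region")
    ref_vals = image.data[ref_mask].mean(axis=0)
    reference = TimeActivityCurve(ref_vals, image.schedule)

    sel = _fit_window(image.schedule, tstar)
    if sel.sum() < 3:
        raise ValueError(f"fewer than 3 frames at or beyond t* = {tstar} min")

    mask = atlas.analysis_mask()
    vox = image.data[mask]  # (n_vox, n_frames)
    ok = np.all(vox[:, sel] > 0, axis=1)
    out = np.full(image.shape3d, np.nan)
    values = np.full(vox.shape[0], np.nan)
    if ok.any():
        x, y = _logan_xy(vox[ok], reference, sel, k2prime)
        slope, _, _ = _ols_line(x, y)
        values[ok] = slope
    n_undef = int(np.sum(~ok))
    if n_undef:
        logger.info("dvr_map: %d of %d voxels undefined (non-positive activity)",
                    n_undef, vox.shape[0])
    out[mask] = values
    return DVRMap(
        data=out,
        affine=image.affine,
        tstar=float(tstar),
        reference_label=atlas.roles["reference_region"],
        k2prime=k2prime,
    )
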