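"""Synthetic dynamic-PET cohort generator.

Forward model
-------------
Every voxel's time-activity curve is generated by the simplified reference
tissue model (SRTM):

    C_T(t) = R1 * C_R(t) + (k2 - R1 * k2a) * [C_R (*) exp(-k2a t)](t),
    k2a = k2 / (1 + BP),

with the reference input C_R(t) = A * t * exp(-t / tau), a gamma-variate bolus
shape.  BP is set per atlas label from the target DVR (BP = DVR - 1); R1 = 1
and k2 = 0.4 /min are fixed defaults, so group differences live entirely in
the binding term that the Logan analysis is meant to recover.

Noise is zero-mean Gaussian per voxel and frame with
SD = noise_scale * sqrt(max(signal, eps) / frame_duration_min) — variance
proportional to signal and inversely proportional to frame duration, the
usual post-reconstruction approximation of counting statistics.

The default cohort design mirrors the study conditions: groups CH/DELIRIUM/
DEMENTIA/DSD of sizes 7/4/4/4; choroid-plexus DVR 0.856 / 0.601 / 0.614 /
0.559 by group with all other regions at DVR 1.0 in every group; MoCA scores
drawn per group (means 19.9 / 6.5 / 6.0 / 5.3, SDs 4.62 / 4.95 / 1.73 /
2.01); the remaining eight assessments are independent noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .imaging_io import ASSESSMENTS, Cohort, DynamicImage, FrameSchedule, LabelAtlas
from .logan_kinetics import TimeActivityCurve

__all__ = [
    "SRTMParams",
    "CohortDesign",
    "ACQUISITION_FRAME_STARTS",
    "ACQUISITION_FRAME_DURATIONS",
    "acquisition_schedule",
    "make_toy_atlas",
    "reference_tac",
    "reference_curve_fine",
    "srtm_tac",
    "simulate_subject",
    "simulate_cohort",
]

# 22-frame / 60-min acquisition: 4x30 s + 4x60 s + 4x120 s + 4x240 s + 6x300 s.
ACQUISITION_FRAME_DURATIONS = np.array([30.0] * 4 + [60.0] * 4 + [120.0] * 4
                                 + [240.0] * 4 + [300.0] * 6)
ACQUISITION_FRAME_STARTS = np.concatenate([[0.0], np.cumsum(ACQUISITION_FRAME_DURATIONS)[:-1]])


def acquisition_schedule() -> FrameSchedule:
    """The 22-frame, 60-minute acquisition schedule."""
    return FrameSchedule(ACQUISITION_FRAME_STARTS.copy(), ACQUISITION_FRAME_DURATIONS.copy())


@dataclass(frozen=True)
class SRTMParams:
    """SRTM kinetic parameters; DVR = 1 + BP."""

    R1: float = 1.0
    k2: float = 0.4  # 1/min
    BP: float = 0.0

    def __post_init__(self) -> None:
        if self.R1 <= 0:
            raise ValueError("R1 must be positive")
        if self.k2 <= 0:
            raise ValueError("k2 must be positive")
        if self.BP <= -1:
            raise ValueError("BP must exceed -1 (DVR must be positive)")

    @property
    def dvr(self) -> float:
        return 1.0 + self.BP

    @property
    def k2a(self) -> float:
        return self.k2 / (1.0 + self.BP)


# Study-condition defaults: group sizes, choroid-plexus DVR and MoCA moments.
_DEFAULT_SIZES = {"CH": 7, "DELIRIUM": 4, "DEMENTIA": 4, "DSD": 4}
_DEFAULT_CP_DVR = {"CH": 0.856, "DELIRIUM": 0.601, "DEMENTIA": 0.614, "DSD": 0.559}
_DEFAULT_MOCA = {
    "CH": (19.9, 4.62),
    "DELIRIUM": (6.5, 4.95),
    "DEMENTIA": (6.0, 1.73),
    "DSD": (5.3, 2.01),
}


def _default_group_dvr() -> dict[str, dict[str, float]]:
    return {
        g: {
            "reference_region": 1.0,
            "gray_matter_mask": 1.0,
            "white_matter_mask": 1.0,
            "subcortical_mask": 1.0,
            "choroid_plexus": cp,
        }
        for g, cp in _DEFAULT_CP_DVR.items()
    }


@dataclass
class CohortDesign:
    """Simulation design: group sizes, true DVR per role per group, MoCA moments."""

    group_sizes: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_SIZES))
    group_dvr: dict[str, dict[str, float]] = field(default_factory=_default_group_dvr)
    moca: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(_DEFAULT_MOCA))
    noise_scale: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 0:
                raise ValueError(f"negative group size for {g}")
        for g, (m, s) in self.moca.items():
            if s < 0:
                raise ValueError(f"negative MoCA SD for {g}")
        for g, dvrs in self.group_dvr.items():
            for role, d in dvrs.items():
                if d <= 0:
                    raise ValueError(f"non-positive DVR for {g}/{role}")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")

    @property
    def n_subjects(self) -> int:
        return sum(self.group_sizes.values())


def make_toy_atlas(shape: tuple[int, int, int] = (32, 32, 32)) -> LabelAtlas:
    """Deterministic labeled phantom hosting all five atlas roles.

    Stand-in for an anatomical parcellation: a cerebellar-gray reference
    block, a gray-matter shell, a white-matter core, a subcortical slab, and
    a choroid-plexus block inside the subcortical territory — pairwise
    disjoint.  At 32^3 the choroid plexus holds 216 voxels.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or min(shape) < 16:
        raise ValueError(f"shape must be >= 16 per axis, got {shape}")
    nx, ny, nz = shape
    labels = np.zeros(shape, dtype=np.int32)

    def box(a, b, c, d, e, f):
        return (slice(a, b), slice(c, d), slice(e, f))

    # gray-matter box; white core and subcortical slab carved out of it below
    labels[box(nx // 4, nx - nx // 4, ny // 4, ny - ny // 4, nz // 4, nz - nz // 4)] = 2
    # white-matter core
    labels[box(3 * nx // 8, 5 * nx // 8, 3 * ny // 8, 5 * ny // 8,
               3 * nz // 8, 5 * nz // 8)] = 3
    # subcortical slab (pokes below the gray box; overwrite keeps disjointness)
    labels[box(3 * nx // 8, 5 * nx // 8, 3 * ny // 8, 5 * ny // 8,
               nz // 16, nz // 16 + nz // 4)] = 4
    # choroid plexus inside the subcortical slab
    cx, cy, cz = (max(3, 6 * n // 32) for n in (nx, ny, nz))
    labels[box(3 * nx // 8 + 1, 3 * nx // 8 + 1 + cx,
               3 * ny // 8 + 1, 3 * ny // 8 + 1 + cy,
               nz // 16 + 1, nz // 16 + 1 + cz)] = 5
    # cerebellar-gray reference block in a free corner
    labels[box(1, 1 + nx // 4, 1, 1 + ny // 4, 1, 1 + nz // 4)] = 1

    counts = {lid: int(np.sum(labels == lid)) for lid in range(1, 6)}
    if min(counts.values()) < 25:
        raise ValueError(f"shape {shape} too small to host all regions: {counts}")

    affine = np.diag([2.0, 2.0, 2.0, 1.0])  # 2 mm isotropic, RAS
    names = {1: "cerebellar_gray", 2: "gray_matter", 3: "white_matter",
             4: "subcortical", 5: "choroid_plexus"}
    roles = {"reference_region": 1, "gray_matter_mask": 2, "white_matter_mask": 3,
             "subcortical_mask": 4, "choroid_plexus": 5}
    return LabelAtlas(labels=labels, affine=affine, names=names, roles=roles)


def reference_tac(schedule: FrameSchedule, A: float = 1.0, tau: float = 15.0
                  ) -> TimeActivityCurve:
    """Frame-averaged reference TAC C_R(t) = A * t * exp(-t/tau), tau in min.

    Frame averages are computed analytically from the closed-form primitive
    F(T) = A * tau^2 * (1 - exp(-T/tau) * (1 + T/tau)).
    """
    if A <= 0 or tau <= 0:
        raise ValueError("A and tau must be positive")
    t0 = schedule.start / 60.0
    t1 = schedule.end / 60.0

    def primitive(t):
        return A * tau**2 * (1.0 - np.exp(-t / tau) * (1.0 + t / tau))

    means = (primitive(t1) - primitive(t0)) / (t1 - t0)
    return TimeActivityCurve(means, schedule)


def reference_curve_fine(schedule: FrameSchedule, A: float = 1.0, tau: float = 15.0,
                         dt_sec: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Time-resolved reference curve on a uniform fine grid (times in min)."""
    if A <= 0 or tau <= 0:
        raise ValueError("A and tau must be positive")
    if dt_sec > 1.0:
        raise ValueError("fine grid must be <= 1 s resolution")
    total_min = schedule.total_duration / 60.0
    n = int(np.ceil(total_min * 60.0 / dt_sec)) + 1
    t = np.arange(n) * (dt_sec / 60.0)
    return t, A * t * np.exp(-t / tau)


def _frame_average(t_min: np.ndarray, values: np.ndarray,
                   schedule: FrameSchedule) -> np.ndarray:
    """Average a fine-grid curve over each frame via its cumulative integral."""
    from scipy.integrate import cumulative_trapezoid

    cum = np.concatenate([[0.0], cumulative_trapezoid(values, t_min)])
    f0 = np.interp(schedule.start / 60.0, t_min, cum)
    f1 = np.interp(schedule.end / 60.0, t_min, cum)
    return (f1 - f0) / (schedule.duration / 60.0)


def srtm_tac(reference_fine: tuple[np.ndarray, np.ndarray], params: SRTMParams,
             schedule: FrameSchedule) -> TimeActivityCurve:
    """SRTM forward solution, frame-averaged.

    ``reference_fine`` is a (times_min, values) pair on a uniform grid of
    <= 1 s resolution.  The convolution C_R (*) exp(-k2a t) is evaluated with
    an exponential-integrator recursion that is exact for piecewise-linear
    C_R, then the target curve is averaged over each frame.
    """
    t, cref = reference_fine
    t = np.asarray(t, float)
    cref = np.asarray(cref, float)
    dt = t[1] - t[0]
    if not np.allclose(np.diff(t), dt, rtol=1e-6):
        raise ValueError("reference curve must be on a uniform grid")
    if dt * 60.0 > 1.0 + 1e-9:
        raise ValueError("reference curve must be sampled at <= 1 s resolution")
    lam = params.k2a
    # x_i = alpha*x_{i-1} + a*cref_{i-1} + b*cref_i, exact for linear cref
    alpha = np.exp(-lam * dt)
    b = 1.0 / lam - (1.0 - alpha) / (lam * lam * dt)
    a = (1.0 - alpha) / lam - b
    conv = lfilter([b, a], [1.0, -alpha], cref)
    ct = params.R1 * cref + (params.k2 - params.R1 * lam) * conv
    return TimeActivityCurve(_frame_average(t, ct, schedule), schedule)


def simulate_subject(
    atlas: LabelAtlas,
    label_dvr: dict[int, float],
    schedule: FrameSchedule,
    noise_scale: float = 0.05,
    seed: int | np.random.SeedSequence = 0,
    R1: float = 1.0,
    k2: float = 0.4,
    ref_amplitude: float = 1.0,
    ref_tau: float = 15.0,
) -> DynamicImage:
    """Simulate one subject's dynamic image from per-label true DVR values.

    Every voxel of a label gets the SRTM TAC with BP = DVR - 1 plus
    independent Gaussian noise; the reference label is forced to DVR 1;
    background stays zero.  Reproducible for a given seed.
    """
    rng = np.random.default_rng(seed)
    fine = reference_curve_fine(schedule, A=ref_amplitude, tau=ref_tau)
    labels_present = sorted(set(np.unique(atlas.labels).tolist()) - {0})
    missing = [lid for lid in labels_present if lid not in label_dvr]
    ref_label = atlas.roles["reference_region"]
    if ref_label in missing:
        missing.remove(ref_label)
    if missing:
        raise ValueError(f"no DVR entry for atlas labels {missing}")

    data = np.zeros(atlas.labels.shape + (schedule.n_frames,))
    for lid in labels_present:
        dvr = 1.0 if lid == ref_label else float(label_dvr[lid])
        tac = srtm_tac(fine, SRTMParams(R1=R1, k2=k2, BP=dvr - 1.0), schedule)
        data[atlas.labels == lid] = tac.values

    if noise_scale > 0:
        dur_min = schedule.duration / 60.0
        sd = noise_scale * np.sqrt(np.maximum(data, 1e-6) / dur_min)
        data = data + rng.standard_normal(data.shape) * sd
    return DynamicImage(data=data, affine=atlas.affine, schedule=schedule)


def _roles_to_labels(atlas: LabelAtlas, role_dvr: dict[str, float]) -> dict[int, float]:
    return {atlas.roles[role]: d for role, d in role_dvr.items()}


def simulate_cohort(
    design: CohortDesign,
    atlas: LabelAtlas,
    schedule: FrameSchedule,
) -> tuple[dict[str, DynamicImage], Cohort]:
    """Simulate a full cohort: one dynamic image per subject plus the table.

    Child seeds are spawned deterministically from ``design.seed``; MoCA is
    drawn per group from the design moments (clipped to the 0-30 score
    range), the other eight assessments as independent standard-normal
    placeholders.
    """
    ss = np.random.SeedSequence(design.seed)
    score_rng = np.random.default_rng(ss.spawn(1)[0])
    subject_ss = ss.spawn(design.n_subjects)

    images: dict[str, DynamicImage] = {}
    rows = []
    i = 0
    for group in sorted(design.group_sizes):
        n = design.group_sizes[group]
        label_dvr = _roles_to_labels(atlas, design.group_dvr[group])
        for j in range(n):
            sid = f"sub-{group}{j + 1:02d}"
            images[sid] = simulate_subject(
                atlas, label_dvr, schedule,
                noise_scale=design.noise_scale, seed=subject_ss[i],
            )
            mean, sd = design.moca[group]
            moca = float(np.clip(score_rng.normal(mean, sd), 0.0, 30.0))
            row = {"subject_id": sid, "group": group,
                   "movement_artifact": False, "technical_issue": False}
            for a in ASSESSMENTS:
                row[a] = float(score_rng.standard_normal())
            # the design-drawn MoCA score is carried by the attention
            # assessment; the other eight stay independent noise so only one
            # regression in the battery tracks the DVR group structure
            row["MoCA_attention"] = moca
            rows.append(row)
            i += 1
    return images, Cohort(pd.DataFrame(rows))
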