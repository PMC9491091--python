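"""Domain types and file I/O for the dynamic-PET pipeline.

All volumes in one analysis share a single voxel grid and affine (spatial
registration is out of scope); a mismatch is an error, never a resample.
Voxel indices are 0-based and the affine maps voxel -> world RAS in mm.
Frame timing follows the BIDS-PET sidecar convention: arrays of frame start
times and frame durations, both in seconds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger("neuropet")

__all__ = [
    "FormatError",
    "FrameSchedule",
    "DynamicImage",
    "LabelAtlas",
    "Cohort",
    "GROUPS",
    "ASSESSMENTS",
    "ROLES",
    "read_frame_schedule",
    "write_frame_schedule",
    "read_dynamic_image",
    "write_dynamic_image",
    "read_label_atlas",
    "write_label_atlas",
    "read_cohort",
    "write_cohort",
    "check_same_grid",
]


class FormatError(ValueError):
    """Raised when an input file violates the expected format or invariants."""


# Cohort vocabulary: the four diagnostic groups and the nine cognitive /
# clinical assessments entering the regression battery.
GROUPS = ("CH", "DELIRIUM", "DEMENTIA", "DSD")
ASSESSMENTS = (
    "CAM",
    "MoCA_execution",
    "MoCA_attention",
    "MoCA_memory",
    "MoCA_language",
    "MoCA_orientation",
    "IQCODE_SF",
    "GDS",
    "NPI",
)

# Reserved atlas roles.  ``subcortical_mask`` is the subcortical tissue label
# proper; the analysis-level subcortical mask additionally includes the
# choroid-plexus label (a ventricular structure counted as subcortical
# tissue), see :meth:`LabelAtlas.tissue_mask`.
ROLES = (
    "reference_region",
    "gray_matter_mask",
    "white_matter_mask",
    "subcortical_mask",
    "choroid_plexus",
)


@dataclass(frozen=True)
class FrameSchedule:
    """Acquisition frame timing: per-frame start times and durations (seconds).

    Frames must be contiguous (each starts where the previous ends),
    non-overlapping, strictly positive in duration, and at least 3 in number
    (a graphical-analysis fit needs >= 3 points).
    """

    start: np.ndarray
    duration: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.start, dtype=float)
        duration = np.asarray(self.duration, dtype=float)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "duration", duration)
        if start.ndim != 1 or duration.ndim != 1 or start.size != duration.size:
            raise FormatError("frame start and duration arrays must be 1-D and equal length")
        if start.size < 3:
            raise FormatError(f"schedule needs >= 3 frames, got {start.size}")
        bad = np.nonzero(duration <= 0)[0]
        if bad.size:
            raise FormatError(f"non-positive duration at frame {bad[0]}")
        gaps = start[1:] - (start[:-1] + duration[:-1])
        bad = np.nonzero(np.abs(gaps) > 1e-9)[0]
        if bad.size:
            raise FormatError(
                f"non-contiguous frames: frame {bad[0] + 1} starts at "
                f"{start[bad[0] + 1]} s but frame {bad[0]} ends at "
                f"{start[bad[0]] + duration[bad[0]]} s"
            )

    @property
    def n_frames(self) -> int:
        return int(self.start.size)

    @property
    def end(self) -> np.ndarray:
        """Frame end times, seconds."""
        return self.start + self.duration

    @property
    def mid(self) -> np.ndarray:
        """Frame mid-times, seconds."""
        return self.start + self.duration / 2.0

    @property
    def total_duration(self) -> float:
        """Total scan duration in seconds (equals the last frame end)."""
        return float(self.end[-1])


@dataclass
class DynamicImage:
    """4-D frame-averaged activity volume with its frame schedule and affine."""

    data: np.ndarray
    affine: np.ndarray
    schedule: FrameSchedule

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 4:
            raise FormatError(f"expected 4D activity volume, got {self.data.ndim}D")
        if self.data.shape[3] != self.schedule.n_frames:
            raise FormatError(
                f"frame-count mismatch: image has {self.data.shape[3]} frames, "
                f"schedule has {self.schedule.n_frames}"
            )
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine)) < 1e-12:
            raise FormatError("affine must be an invertible 4x4 matrix")
        n_neg = int(np.sum(self.data < 0))
        if n_neg:
            logger.info("clipping %d negative voxels to 0", n_neg)
            np.clip(self.data, 0, None, out=self.data)

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class LabelAtlas:
    """Integer label volume (0 = background) with a label dictionary.

    ``names`` maps label id -> region name; ``roles`` maps each reserved role
    to its label id.  All five roles must be present in the volume.
    """

    labels: np.ndarray
    affine: np.ndarray
    names: dict[int, str]
    roles: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise FormatError("atlas volume must be integer-typed")
        if self.labels.ndim != 3:
            raise FormatError(f"expected 3D label volume, got {self.labels.ndim}D")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        present = set(np.unique(self.labels).tolist())
        for role in ROLES:
            if role not in self.roles:
                raise FormatError(f"atlas dictionary lacks role '{role}'")
            if self.roles[role] not in present:
                raise FormatError(
                    f"role '{role}' label {self.roles[role]} absent from volume"
                )
        orphans = sorted(set(self.names) - present - {0})
        if orphans:
            logger.warning(
                "dictionary labels absent from volume (ignored in ROI tables): %s",
                orphans,
            )

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def role_mask(self, role: str) -> np.ndarray:
        return self.mask(self.roles[role])

    def tissue_mask(self, tissue: str) -> np.ndarray:
        """Analysis mask for one of 'gray', 'white', 'subcortical'.

        The subcortical mask is the union of the subcortical label and the
        choroid-plexus label (choroid plexus sits inside the ventricular
        subcortical territory).
        """
        if tissue == "gray":
            return self.role_mask("gray_matter_mask")
        if tissue == "white":
            return self.role_mask("white_matter_mask")
        if tissue == "subcortical":
            return self.role_mask("subcortical_mask") | self.role_mask("choroid_plexus")
        raise ValueError(f"unknown tissue '{tissue}'")

    def analysis_mask(self) -> np.ndarray:
        """Union of all role regions: the voxels quantified by the pipeline."""
        out = np.zeros(self.labels.shape, dtype=bool)
        for role in ROLES:
            out |= self.role_mask(role)
        return out

    @property
    def present_labels(self) -> list[int]:
        """Non-background labels present in both volume and dictionary."""
        present = set(np.unique(self.labels).tolist()) - {0}
        return sorted(present & set(self.names))


class Cohort:
    """Subject table: id, diagnostic group, nine assessments, QC flags.

    QC-excluded subjects are retained in the table but flagged; the analysis
    set is :meth:`qc_passed`.
    """

    QC_FLAGS = ("movement_artifact", "technical_issue")

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        if "subject_id" not in table.columns or "group" not in table.columns:
            raise FormatError("cohort table needs 'subject_id' and 'group' columns")
        if len(table) == 0:
            raise FormatError("cohort table is empty")
        dup = table["subject_id"][table["subject_id"].duplicated()]
        if len(dup):
            raise FormatError(f"duplicate subject id: {dup.iloc[0]!r}")
        if table["group"].isna().any():
            raise FormatError("missing group label")
        unknown = set(table["group"]) - set(GROUPS)
        if unknown:
            raise FormatError(f"unknown group labels: {sorted(unknown)}")
        for flag in self.QC_FLAGS:
            if flag not in table.columns:
                table[flag] = False
            table[flag] = table[flag].fillna(False).astype(bool)
        for a in ASSESSMENTS:
            if a not in table.columns:
                table[a] = np.nan
        self.table = table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def subject_ids(self) -> list[str]:
        return self.table["subject_id"].tolist()

    def qc_passed(self) -> pd.DataFrame:
        """Rows passing QC (no movement artifact, no technical issue)."""
        ok = ~(self.table["movement_artifact"] | self.table["technical_issue"])
        return self.table[ok].reset_index(drop=True)

    def group_of(self, subject_id: str) -> str:
        row = self.table[self.table["subject_id"] == subject_id]
        if len(row) == 0:
            raise KeyError(subject_id)
        return row["group"].iloc[0]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_frame_schedule(path: str | Path) -> FrameSchedule:
    """Read a BIDS-PET style JSON sidecar with FrameTimesStart/FrameDuration."""
    with open(path) as fh:
        obj = json.load(fh)
    try:
        start = obj["FrameTimesStart"]
        duration = obj["FrameDuration"]
    except KeyError as exc:
        raise FormatError(f"timing sidecar lacks key {exc}") from None
    return FrameSchedule(np.asarray(start, float), np.asarray(duration, float))


def write_frame_schedule(schedule: FrameSchedule, path: str | Path) -> None:
    obj = {
        "FrameTimesStart": schedule.start.tolist(),
        "FrameDuration": schedule.duration.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)


def read_dynamic_image(image_path: str | Path, timing_path: str | Path) -> DynamicImage:
    schedule = read_frame_schedule(timing_path)
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise FormatError(f"expected 4D image, got {data.ndim}D")
    return DynamicImage(data=data, affine=np.asarray(img.affine), schedule=schedule)


def write_dynamic_image(image: DynamicImage, image_path: str | Path,
                        timing_path: str | Path | None = None) -> None:
    nib.save(
        nib.Nifti1Image(image.data.astype(np.float32), image.affine),
        str(image_path),
    )
    if timing_path is not None:
        write_frame_schedule(image.schedule, timing_path)


def read_label_atlas(labels_path: str | Path, dictionary_path: str | Path) -> LabelAtlas:
    """Read an integer NIfTI label volume plus a TSV dictionary (id, name, role)."""
    img = nib.load(str(labels_path))
    data = np.asarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        if np.allclose(data, np.round(data)):
            data = np.round(data).astype(np.int32)
        else:
            raise FormatError("atlas volume is not integer-valued")
    table = pd.read_csv(dictionary_path, sep="\t")
    for col in ("id", "name"):
        if col not in table.columns:
            raise FormatError(f"label dictionary lacks column '{col}'")
    names = dict(zip(table["id"].astype(int), table["name"].astype(str)))
    roles: dict[str, int] = {}
    if "role" in table.columns:
        for _, row in table.iterrows():
            role = row.get("role")
            if isinstance(role, str) and role.strip():
                roles[role.strip()] = int(row["id"])
    return LabelAtlas(labels=data.astype(np.int32), affine=np.asarray(img.affine),
                      names=names, roles=roles)


def write_label_atlas(atlas: LabelAtlas, labels_path: str | Path,
                      dictionary_path: str | Path) -> None:
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int16), atlas.affine),
             str(labels_path))
    role_of = {v: k for k, v in atlas.roles.items()}
    rows = [
        {"id": lid, "name": name, "role": role_of.get(lid, "")}
        for lid, name in sorted(atlas.names.items())
    ]
    pd.DataFrame(rows).to_csv(dictionary_path, sep="\t", index=False)


def read_cohort(path: str | Path) -> Cohort:
    try:
        table = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise FormatError(f"cohort file {path} is empty") from None
    return Cohort(table)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    cohort.table.to_csv(path, sep="\t", index=False)


def check_same_grid(*objs) -> None:
    """Assert that images/atlases share shape and affine; error otherwise."""
    shapes, affines = [], []
    for o in objs:
        if isinstance(o, DynamicImage):
            shapes.append(o.shape3d)
            affines.append(o.affine)
        elif isinstance(o, LabelAtlas):
            shapes.append(o.labels.shape)
            affines.append(o.affine)
        else:  # (shape, affine) pair or raw DVR-map-like object
            shapes.append(tuple(o.shape) if hasattr(o, "shape") else tuple(o[0]))
            affines.append(getattr(o, "affine", None) if hasattr(o, "affine") else o[1])
    for s, a in zip(shapes[1:], affines[1:]):
        if s != shapes[0]:
            raise FormatError(f"grid shape mismatch: {s} vs {shapes[0]}")
        if a is not None and affines[0] is not None and not np.allclose(a, affines[0], atol=1e-6):
            raise FormatError("affine mismatch between volumes")
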