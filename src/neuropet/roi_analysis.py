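"""ROI statistics on DVR maps and significance-mask / atlas overlap."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .imaging_io import FormatError, LabelAtlas
from .logan_kinetics import DVRMap

logger = logging.getLogger("neuropet")

__all__ = ["roi_means", "highest_overlap_label", "cohort_roi_table"]


def roi_means(dvr: DVRMap, atlas: LabelAtlas) -> pd.DataFrame:
    """Per-label DVR statistics: n_voxels, n_defined, mean, SD.

    NaN (undefined) voxels are excluded from means; a label with zero
    defined voxels gets a missing mean.  Labels present in the volume but
    absent from the dictionary are ignored (warned at load time).
    """
    if dvr.data.shape != atlas.labels.shape:
        raise FormatError(
            f"grid mismatch: map {dvr.data.shape} vs atlas {atlas.labels.shape}"
        )
    rows = []
    for lid in atlas.present_labels:
        vals = dvr.data[atlas.labels == lid]
        defined = vals[np.isfinite(vals)]
        rows.append({
            "label": lid,
            "name": atlas.names[lid],
            "n_voxels": int(vals.size),
            "n_defined": int(defined.size),
            "mean_dvr": float(defined.mean()) if defined.size else np.nan,
            "sd_dvr": float(defined.std(ddof=1)) if defined.size > 1 else np.nan,
        })
    return pd.DataFrame(rows)


def highest_overlap_label(sig_mask: np.ndarray, atlas: LabelAtlas
                          ) -> tuple[int, pd.DataFrame]:
    """Atlas label (excluding background) with the most significant voxels.

    Overlap is a plain voxel count, not a fraction of region size.  Ties are
    broken toward the smallest label id with a warning.  An empty mask is an
    error.
    """
    sig_mask = np.asarray(sig_mask, dtype=bool)
    if sig_mask.shape != atlas.labels.shape:
        raise FormatError("significance mask and atlas grids differ")
    if not sig_mask.any():
        raise ValueError("empty significance mask")
    hit = atlas.labels[sig_mask]
    counts = np.bincount(hit[hit > 0], minlength=int(atlas.labels.max()) + 1)
    table = pd.DataFrame({
        "label": np.arange(counts.size),
        "overlap_voxels": counts,
    }).query("label > 0 and overlap_voxels > 0").reset_index(drop=True)
    if len(table) == 0:
        raise ValueError("significance mask overlaps only background")
    best = int(table.loc[table["overlap_voxels"].idxmax(), "label"])
    top = table[table["overlap_voxels"] == table["overlap_voxels"].max()]
    if len(top) > 1:
        best = int(top["label"].min())
        logger.warning("overlap tie between labels %s; choosing %d",
                       top["label"].tolist(), best)
    table["name"] = [atlas.names.get(int(l), "") for l in table["label"]]
    return best, table


def cohort_roi_table(maps_by_subject: dict[str, DVRMap], atlas: LabelAtlas
                     ) -> pd.DataFrame:
    """Wide table of per-subject ROI mean DVR (subjects x label names)."""
    rows = {}
    for sid, m in maps_by_subject.items():
        t = roi_means(m, atlas)
        rows[sid] = dict(zip(t["name"], t["mean_dvr"]))
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out.index.name = "subject_id"
    return out
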