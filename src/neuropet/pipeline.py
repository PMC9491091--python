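"""End-to-end orchestration: simulate -> DVR -> ROI -> voxelwise -> regression.

One YAML config drives the run; every stage writes its outputs into a
subdirectory of the run directory and the whole run is summarized in
``summary.json`` plus a ``manifest.json`` with versions and seeds.  All
randomness derives from one master seed, so a rerun with the same config is
reproducible.

Reduced defaults (16^3 grid, 500 permutations) keep a full run at desk
scale; ``full_scale: true`` switches to 32^3 and 5000 permutations.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .association_stats import run_assessment_battery
from .imaging_io import (
    Cohort,
    GROUPS,
    read_cohort,
    read_dynamic_image,
    read_label_atlas,
    write_cohort,
    write_dynamic_image,
    write_label_atlas,
)
from .logan_kinetics import DVRMap, dvr_map
from .roi_analysis import cohort_roi_table, highest_overlap_label, roi_means
from .synthetic_cohort import CohortDesign, make_toy_atlas, acquisition_schedule, simulate_cohort
from .voxelwise_inference import TFCEConfig, permutation_fwe

logger = logging.getLogger("neuropet")

__all__ = ["default_config", "run_pipeline"]

TISSUES = ("gray", "white", "subcortical")
IMPAIRED = ("DELIRIUM", "DEMENTIA", "DSD")


def default_config(full_scale: bool = False) -> dict:
    """The bundled default configuration (19-subject study design)."""
    return {
        "seed": 7,
        "grid": [32, 32, 32] if full_scale else [16, 16, 16],
        "n_perm": 5000 if full_scale else 500,
        "alpha": 0.05,
        "tstar": 30.0,
        "k2prime": None,
        "noise_scale": 0.05,
        "group_sizes": {"CH": 7, "DELIRIUM": 4, "DEMENTIA": 4, "DSD": 4},
        "choroid_dvr": {"CH": 0.856, "DELIRIUM": 0.601,
                        "DEMENTIA": 0.614, "DSD": 0.559},
        "directions": ["A>B", "B>A"],
        "inputs": None,
    }


def _load_config(config_path) -> dict:
    if isinstance(config_path, dict):
        user = dict(config_path)
    else:
        with open(config_path) as fh:
            user = yaml.safe_load(fh) or {}
    cfg = default_config(bool(user.pop("full_scale", False)))
    unknown = set(user) - set(cfg)
    if unknown:
        raise KeyError(f"unknown config keys: {sorted(unknown)}")
    cfg.update(user)
    missing = [k for k in ("seed", "grid", "n_perm", "alpha") if cfg.get(k) is None]
    if missing:
        raise KeyError(f"missing config keys: {missing}")
    return cfg


def _child_seed(master: int, tag: str) -> int:
    import zlib

    ss = np.random.SeedSequence([int(master), zlib.crc32(tag.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def _stage_simulate(cfg: dict, outdir: Path):
    atlas = make_toy_atlas(tuple(cfg["grid"]))
    schedule = acquisition_schedule()
    design = CohortDesign(
        group_sizes=dict(cfg["group_sizes"]),
        noise_scale=float(cfg["noise_scale"]),
        seed=int(cfg["seed"]),
    )
    for g, d in cfg["choroid_dvr"].items():
        design.group_dvr[g]["choroid_plexus"] = float(d)
    images, cohort = simulate_cohort(design, atlas, schedule)
    outdir.mkdir(parents=True, exist_ok=True)
    write_label_atlas(atlas, outdir / "atlas.nii.gz", outdir / "labels.tsv")
    write_cohort(cohort, outdir / "cohort.tsv")
    for sid, img in images.items():
        write_dynamic_image(img, outdir / f"{sid}_pet.nii.gz",
                            outdir / f"{sid}_timing.json")
    return images, cohort, atlas


def _stage_inputs(cfg: dict):
    inp = cfg["inputs"]
    required = {"images", "timing", "cohort", "atlas", "dictionary"}
    missing = required - set(inp)
    if missing:
        raise KeyError(f"missing input keys: {sorted(missing)}")
    atlas = read_label_atlas(inp["atlas"], inp["dictionary"])
    cohort = read_cohort(inp["cohort"])
    images = {
        sid: read_dynamic_image(path, inp["timing"])
        for sid, path in inp["images"].items()
    }
    return images, cohort, atlas


def run_pipeline(config_path, run_dir) -> Path:
    """Run the full analysis described by a YAML config into ``run_dir``.

    Returns the run directory; ``summary.json`` inside it holds per-group
    choroid-plexus DVR means, significant-voxel counts per tissue mask,
    group pair and direction, the highest-overlap region, and the nine
    regression results.
    """
    cfg = _load_config(config_path)
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    # --- stage 1: images + cohort -----------------------------------------
    if cfg["inputs"]:
        images, cohort, atlas = _stage_inputs(cfg)
    else:
        images, cohort, atlas = _stage_simulate(cfg, run_dir / "simulate")

    qc = cohort.qc_passed()
    subject_ids = qc["subject_id"].tolist()
    group_of = dict(zip(qc["subject_id"], qc["group"]))

    # --- stage 2: voxelwise Logan DVR maps ---------------------------------
    dvr_dir = run_dir / "dvr"
    dvr_dir.mkdir(exist_ok=True)
    maps: dict[str, DVRMap] = {}
    for sid in subject_ids:
        m = dvr_map(images[sid], atlas, tstar=float(cfg["tstar"]),
                    k2prime=cfg["k2prime"])
        maps[sid] = m
        import nibabel as nib
        nib.save(nib.Nifti1Image(m.data.astype(np.float32), m.affine),
                 str(dvr_dir / f"{sid}_dvr.nii.gz"))
        with open(dvr_dir / f"{sid}_dvr.json", "w") as fh:
            json.dump({"tstar_min": m.tstar, "reference_label": m.reference_label,
                       "k2prime": m.k2prime}, fh)

    # --- stage 3: ROI tables ------------------------------------------------
    roi_dir = run_dir / "roi"
    roi_dir.mkdir(exist_ok=True)
    for sid in subject_ids:
        roi_means(maps[sid], atlas).to_csv(roi_dir / f"{sid}_roi.tsv",
                                           sep="\t", index=False)
    wide = cohort_roi_table(maps, atlas)
    wide.to_csv(roi_dir / "roi_wide.tsv", sep="\t")

    cp_name = atlas.names[atlas.roles["choroid_plexus"]]
    group_cp_means = {
        g: float(np.nanmean([wide.loc[s, cp_name] for s in subject_ids
                             if group_of[s] == g]))
        for g in GROUPS if any(group_of[s] == g for s in subject_ids)
    }

    # --- stage 4: voxelwise permutation inference ---------------------------
    vox_dir = run_dir / "voxelstats"
    vox_dir.mkdir(exist_ok=True)
    sig_counts: dict[str, int] = {}
    subcortical_pos_sig = np.zeros(atlas.labels.shape, dtype=bool)
    for tissue in TISSUES:
        mask = atlas.tissue_mask(tissue)
        for grp in IMPAIRED:
            a_ids = [s for s in subject_ids if group_of[s] == "CH"]
            b_ids = [s for s in subject_ids if group_of[s] == grp]
            if len(a_ids) < 2 or len(b_ids) < 2:
                logger.warning("skipping CH vs %s (degenerate group)", grp)
                continue
            for direction in cfg["directions"]:
                tag = f"{tissue}_CHvs{grp}_{direction.replace('>', 'gt')}"
                tcfg = TFCEConfig(
                    n_perm=int(cfg["n_perm"]), alpha=float(cfg["alpha"]),
                    direction=direction, seed=_child_seed(seed, tag),
                )
                res = permutation_fwe(
                    [maps[s] for s in a_ids] + [maps[s] for s in b_ids],
                    ["CH"] * len(a_ids) + [grp] * len(b_ids),
                    mask, tcfg, groups=("CH", grp),
                )
                sig_counts[tag] = res.n_significant
                if tissue == "subcortical" and direction == "A>B":
                    subcortical_pos_sig |= res.sig_mask
                with open(vox_dir / f"{tag}.json", "w") as fh:
                    json.dump({
                        "n_significant": res.n_significant,
                        "min_p_fwe": float(np.nanmin(res.p_fwe_map)),
                        "max_tfce": float(res.tfce_map.max()),
                        "n_perm_effective": int(res.null_max.size),
                        "exhaustive": bool(res.exhaustive_used),
                    }, fh, indent=1)

    # --- stage 5: highest-overlap region and regression battery -------------
    reg_dir = run_dir / "regress"
    reg_dir.mkdir(exist_ok=True)
    summary: dict = {
        "config": {k: v for k, v in cfg.items() if k != "inputs"},
        "n_subjects": len(subject_ids),
        "group_choroid_plexus_dvr": group_cp_means,
        "significant_voxels": sig_counts,
    }
    if subcortical_pos_sig.any():
        label, overlap = highest_overlap_label(subcortical_pos_sig, atlas)
        overlap.to_csv(reg_dir / "overlap.tsv", sep="\t", index=False)
        roi_name = atlas.names[label]
        roi_vals = {}
        for sid in subject_ids:
            vals = maps[sid].data[atlas.labels == label]
            vals = vals[np.isfinite(vals)]
            roi_vals[sid] = float(vals.mean()) if vals.size else np.nan
        results, diagnostics = run_assessment_battery(cohort, roi_vals)
        results.to_csv(reg_dir / "regressions.tsv", sep="\t", index=False)
        diagnostics.to_csv(reg_dir / "diagnostics.tsv", sep="\t", index=False)
        summary["highest_overlap"] = {"label": label, "name": roi_name}
        summary["regressions"] = results.replace({np.nan: None}).to_dict("records")
    else:
        summary["highest_overlap"] = None
        summary["regressions"] = []
        logger.warning("no significant subcortical voxels; regression skipped")

    with open(run_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=float)
    with open(run_dir / "manifest.json", "w") as fh:
        json.dump({"neuropet_version": __version__, "numpy": np.__version__,
                   "master_seed": seed}, fh, indent=1)
    return run_dir
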