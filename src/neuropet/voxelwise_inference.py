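"""Voxelwise two-sample permutation inference with TFCE and max-statistic FWE.

The observed statistic is an unpaired pooled-variance t map, enhanced by
threshold-free cluster enhancement (TFCE):

    TFCE(v) = sum over h = dh, 2dh, ..., <= stat(v) of  e(h, v)^E * h^H * dh,

where e(h, v) is the size of the connected component containing v among
voxels with stat >= h.  Family-wise error is controlled by comparing each
voxel's observed TFCE score with the permutation distribution of the
image-wide maximum TFCE under random relabelings of group membership.

Each direction (A>B, B>A) is a separate one-sided run with its own
correction; negative-going statistic voxels contribute nothing to a run's
TFCE map.  No spatial or variance smoothing is applied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import ndimage

from .logan_kinetics import DVRMap

logger = logging.getLogger("neuropet")

__all__ = ["TFCEConfig", "TFCEResult", "tstat_map", "tfce_transform", "permutation_fwe"]

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class TFCEConfig:
    """Settings for TFCE permutation inference.

    dh = None selects the adaptive step (max statistic / 100); a fixed dh is
    mainly for oracle comparisons.  ``exhaustive`` enumerates all distinct
    group relabelings instead of sampling; sampling falls back to exhaustive
    enumeration automatically when the distinct count does not exceed
    ``n_perm``.
    """

    E: float = 0.5
    H: float = 2.0
    dh: float | None = None
    connectivity: int = 26
    n_perm: int = 5000
    seed: int = 0
    alpha: float = 0.05
    direction: str = "A>B"
    exhaustive: bool = False

    def __post_init__(self) -> None:
        if self.E <= 0 or self.H <= 0:
            raise ValueError("TFCE exponents must be positive")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be positive")
        if self.connectivity not in _STRUCTURES:
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.direction not in ("A>B", "B>A"):
            raise ValueError("direction must be 'A>B' or 'B>A'")


@dataclass
class TFCEResult:
    """Observed maps, permutation null and FWE-corrected significance."""

    t_map: np.ndarray
    tfce_map: np.ndarray
    null_max: np.ndarray
    p_fwe_map: np.ndarray
    sig_mask: np.ndarray
    mask: np.ndarray
    config: TFCEConfig
    exhaustive_used: bool = False

    @property
    def n_significant(self) -> int:
        return int(self.sig_mask.sum())


def _as_array(m) -> np.ndarray:
    return m.data if isinstance(m, DVRMap) else np.asarray(m, dtype=float)


def _pooled_t(X: np.ndarray, is_a: np.ndarray) -> np.ndarray:
    """Unpaired pooled-variance t over the first axis of X (subjects)."""
    a = X[is_a]
    b = X[~is_a]
    na, nb = a.shape[0], b.shape[0]
    ma = a.mean(axis=0)
    mb = b.mean(axis=0)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0),
                     np.where(diff == 0, 0.0, np.inf))
    return t


def tstat_map(maps_a, maps_b, mask: np.ndarray) -> np.ndarray:
    """Voxelwise unpaired pooled-variance t map (A minus B) within a mask.

    Voxels where any subject is NaN are dropped from the effective mask and
    returned as NaN.  Each group needs >= 2 subjects.
    """
    A = np.stack([_as_array(m) for m in maps_a])
    B = np.stack([_as_array(m) for m in maps_b])
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("each group needs >= 2 subjects")
    if A.shape[1:] != B.shape[1:] or A.shape[1:] != tuple(mask.shape):
        raise ValueError("grid mismatch between groups or mask")
    X = np.concatenate([A, B])
    eff = np.asarray(mask, bool) & np.all(np.isfinite(X), axis=0)
    if not eff.any():
        raise ValueError("empty effective mask (all voxels NaN or unmasked)")
    is_a = np.zeros(X.shape[0], dtype=bool)
    is_a[: A.shape[0]] = True
    out = np.full(mask.shape, np.nan)
    out[eff] = _pooled_t(X[:, eff], is_a)
    return out


def _tfce_core(stat3d: np.ndarray, E: float, H: float, dh: float | None,
               structure: np.ndarray) -> np.ndarray:
    """TFCE of a non-negative 3D statistic array (zeros outside the mask)."""
    m = float(stat3d.max(initial=0.0))
    out = np.zeros_like(stat3d)
    if m <= 0:
        return out
    step = m / 100.0 if dh is None else dh
    n_steps = int(math.floor(m / step + 1e-9))
    eps = 1e-9 * m
    for k in range(1, n_steps + 1):
        h = k * step
        lab, n = ndimage.label(stat3d >= h - eps, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        out += np.where(lab > 0, sizes[lab] ** E * (h ** H) * step, 0.0)
    return out


def tfce_transform(stat_map: np.ndarray, mask: np.ndarray,
                   config: TFCEConfig = TFCEConfig()) -> np.ndarray:
    """Apply TFCE to a statistic map within a mask.

    Negative or zero statistic values contribute nothing; values inside the
    mask must be finite.  Computation is cropped to the mask bounding box,
    so the result is equivariant under translation of the masked image.
    """
    mask = np.asarray(mask, bool)
    stat_map = np.asarray(stat_map, float)
    if stat_map.shape != mask.shape:
        raise ValueError("stat map and mask shapes differ")
    if not np.all(np.isfinite(stat_map[mask])):
        raise ValueError("non-finite statistic values inside the mask")
    out = np.zeros(mask.shape)
    if not mask.any():
        return out
    sl = ndimage.find_objects(mask.astype(np.int8))[0]
    s = np.where(mask[sl], np.maximum(stat_map[sl], 0.0), 0.0)
    out[sl] = _tfce_core(s, config.E, config.H, config.dh,
                         _STRUCTURES[config.connectivity])
    out[~mask] = 0.0
    return out


def _n_distinct_relabelings(n: int, na: int) -> int:
    return math.comb(n, na)


def permutation_fwe(maps, labels, mask: np.ndarray,
                    config: TFCEConfig = TFCEConfig(),
                    groups: tuple | None = None) -> TFCEResult:
    """Max-TFCE permutation test of group A vs group B within a mask.

    Parameters
    ----------
    maps : sequence of 3D arrays or DVRMap
        One DVR map per subject.
    labels : sequence
        Group membership per subject; exactly two distinct values.  ``groups``
        fixes which is A and which is B (default: order of first appearance).
    mask : 3D boolean
        Analysis mask; NaN voxels of any subject are excluded from it.
    config : TFCEConfig
        Direction "A>B" tests A minus B one-sided (and vice versa).

    The null distribution is the maximum TFCE score over the mask under
    relabelings of group membership.  In exhaustive mode all C(n, nA)
    distinct relabelings form the null (the observed labeling is one of
    them) and p(v) = #{null >= TFCE_obs(v)} / N.  In sampled mode the null
    is ``n_perm`` uniformly random relabelings and the observed labeling
    enters as the "+1": p(v) = (1 + #{null >= TFCE_obs(v)}) / (n_perm + 1).
    Sampling falls back to exhaustive enumeration when N <= n_perm.
    """
    labels = list(labels)
    if groups is None:
        seen = list(dict.fromkeys(labels))
        if len(seen) != 2:
            raise ValueError(f"need exactly 2 groups, got {seen}")
        groups = (seen[0], seen[1])
    ga, gb = groups
    unknown = set(labels) - {ga, gb}
    if unknown:
        raise ValueError(f"labels outside groups {groups}: {unknown}")
    is_a_obs = np.array([l == ga for l in labels], dtype=bool)
    na = int(is_a_obs.sum())
    nb = len(labels) - na
    if na < 2 or nb < 2:
        raise ValueError(f"degenerate groups: nA={na}, nB={nb}")

    X = np.stack([_as_array(m) for m in maps])
    mask = np.asarray(mask, bool)
    eff = mask & np.all(np.isfinite(X), axis=0)
    if not eff.any():
        raise ValueError("empty effective mask")
    dropped = int(mask.sum() - eff.sum())
    if dropped:
        logger.info("permutation_fwe: %d mask voxels dropped (NaN in a subject)",
                    dropped)

    # crop to the effective-mask bounding box: TFCE cost scales with volume
    sl = ndimage.find_objects(eff.astype(np.int8))[0]
    eff_c = eff[sl]
    Xc = X[(slice(None),) + sl]
    Xv = Xc[:, eff_c]  # (n_subj, n_vox)
    sign = 1.0 if config.direction == "A>B" else -1.0
    structure = _STRUCTURES[config.connectivity]

    def tfce_of(is_a: np.ndarray) -> np.ndarray:
        t = sign * _pooled_t(Xv, is_a)
        s = np.zeros(eff_c.shape)
        s[eff_c] = np.maximum(t, 0.0)
        if not np.all(np.isfinite(s)):
            raise ValueError("non-finite t statistic (zero-variance voxel)")
        return _tfce_core(s, config.E, config.H, config.dh, structure)

    obs_tfce_c = tfce_of(is_a_obs)
    obs_t = np.full(mask.shape, np.nan)
    tmp = np.full(eff_c.shape, np.nan)
    tmp[eff_c] = sign * _pooled_t(Xv, is_a_obs)
    obs_t[sl] = tmp

    n_distinct = _n_distinct_relabelings(len(labels), na)
    if config.exhaustive and config.n_perm > n_distinct:
        raise ValueError(
            f"n_perm={config.n_perm} exceeds {n_distinct} distinct relabelings"
        )
    exhaustive = config.exhaustive or n_distinct <= config.n_perm

    if exhaustive:
        null_max = np.empty(n_distinct)
        for i, idx in enumerate(combinations(range(len(labels)), na)):
            is_a = np.zeros(len(labels), dtype=bool)
            is_a[list(idx)] = True
            null_max[i] = tfce_of(is_a).max()
        denom_add = 0  # observed labeling is one of the enumerated relabelings
    else:
        rng = np.random.default_rng(config.seed)
        null_max = np.empty(config.n_perm)
        for i in range(config.n_perm):
            null_max[i] = tfce_of(rng.permutation(is_a_obs)).max()
        denom_add = 1  # observed labeling counted on top of the sampled null

    sorted_null = np.sort(null_max)
    obs_vals = obs_tfce_c[eff_c]
    n_ge = null_max.size - np.searchsorted(sorted_null, obs_vals, side="left")
    p_vals = (denom_add + n_ge) / (null_max.size + denom_add)

    p_map = np.full(mask.shape, np.nan)
    tmp = np.full(eff_c.shape, np.nan)
    tmp[eff_c] = p_vals
    p_map[sl] = tmp
    tfce_map = np.zeros(mask.shape)
    tfce_map[sl] = obs_tfce_c
    sig = np.zeros(mask.shape, dtype=bool)
    sig[sl] = np.where(eff_c, tmp < config.alpha, False)
    return TFCEResult(
        t_map=obs_t, tfce_map=tfce_map, null_max=null_max, p_fwe_map=p_map,
        sig_mask=sig, mask=eff, config=config, exhaustive_used=exhaustive,
    )
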