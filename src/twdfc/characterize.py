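"""Anatomical and functional characterization of connectivity clusters.

Given a group parcellation of the seed ROI, this module quantifies

* the percentage overlap of each atlas nucleus with each cluster,
* inter-subject consistency via maximum probability maps (MPMs) after
  Dice-based matching of individual clusters to group clusters,
* each cluster's whole-brain tw-dFC correlation profile (Fisher z of the
  Pearson correlation between the cluster mean series and every traversed
  voxel's series), made preferential via winner-takes-all assignment,
* group inference on subject maps via a one-sample permutation t-test with
  max-statistic family-wise error control (sign-flipping null), and
* a voxelwise lateralization index LI = (Z_left - Z_right)/(Z_left + Z_right)
  comparing left- and right-seed connectivity at each voxel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import TwDfcImage
from .images import Image3D
from .parcellate import Partition
from .validity import dice

logger = logging.getLogger(__name__)

__all__ = [
    "percent_overlap",
    "overlap_table",
    "mpm",
    "cluster_timecourse_map",
    "cluster_timecourse_maps",
    "winner_takes_all",
    "PermutationResult",
    "permutation_onesample",
    "LateralizationMap",
    "lateralization",
]

_CLAMP = 1.0 - 1e-7


def percent_overlap(cluster_mask: np.ndarray, nucleus_mask: np.ndarray) -> float:
    """Percent of the nucleus volume falling inside the cluster."""
    c = np.asarray(cluster_mask) > 0
    n = np.asarray(nucleus_mask) > 0
    vol = int(n.sum())
    if vol == 0:
        raise ValueError("nucleus mask is empty")
    return 100.0 * int((c & n).sum()) / vol


def overlap_table(
    partition: Partition, atlas: Image3D, shape: tuple[int, int, int] | None = None
):
    """Nucleus x cluster table of percent overlaps (rows: atlas labels)."""
    import pandas as pd

    if shape is None:
        shape = atlas.shape
    labels = sorted(int(v) for v in np.unique(atlas.data) if v != 0)
    rows = {}
    for nuc in labels:
        nmask = np.asarray(atlas.data) == nuc
        rows[nuc] = {
            c: percent_overlap(partition.cluster_mask(c, shape), nmask)
            for c in range(1, partition.k + 1)
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def mpm(
    individual_partitions: list[Partition],
    group_partition: Partition,
    shape: tuple[int, int, int],
) -> dict[int, Image3D | np.ndarray]:
    """Maximum probability maps after individual-to-group cluster matching.

    Each individual cluster is relabelled to the group cluster with the
    highest Dice overlap (many individual clusters may map to one group
    cluster); per group label the binarized individual parcels are averaged
    across subjects, giving the probability of each voxel's assignment.
    Individual clusters with zero Dice to every group cluster are dropped
    (logged).
    """
    group_masks = {
        g: group_partition.cluster_mask(g, shape) for g in range(1, group_partition.k + 1)
    }
    acc = {g: np.zeros(shape, dtype=float) for g in group_masks}
    n_unmatched = 0
    for p in individual_partitions:
        for lab in range(1, p.k + 1):
            m = p.cluster_mask(lab, shape)
            dices = {g: dice(m, gm) for g, gm in group_masks.items()}
            best = max(dices, key=lambda g: (dices[g], -g))
            if dices[best] == 0:
                n_unmatched += 1
                continue
            acc[best] += m
    if n_unmatched:
        logger.info("%d individual cluster(s) had zero Dice to all group clusters", n_unmatched)
    n = len(individual_partitions)
    return {g: a / n for g, a in acc.items()}


def cluster_timecourse_map(twdfc: TwDfcImage, cluster_mask: np.ndarray) -> Image3D:
    """Fisher-z map of correlation between the cluster mean tw-dFC series
    and every traversed voxel's series.

    The cluster time course is the across-voxel mean of the cluster's
    defined tw-dFC values per window; windows where it is undefined are
    dropped jointly.  Untraversed voxels are NaN.
    """
    return cluster_timecourse_maps(twdfc, {1: cluster_mask})[1]


def cluster_timecourse_maps(
    twdfc: TwDfcImage, cluster_masks: dict[int, np.ndarray]
) -> dict[int, Image3D]:
    """Batched :func:`cluster_timecourse_map` for several cluster masks.

    All time courses are correlated with the traversed-voxel series in one
    pass, which is the hot loop of the characterization stage.
    """
    tcs: dict[int, np.ndarray] = {}
    for key, cluster_mask in cluster_masks.items():
        m = np.asarray(cluster_mask) > 0
        if not m.any():
            raise ValueError("cluster mask is empty")
        series = twdfc.data[m]  # (n_cluster_voxels, W)
        valid = np.isfinite(series)
        cnt = valid.sum(axis=0)
        mean_tc = np.where(cnt > 0, np.where(valid, series, 0.0).sum(axis=0), np.nan)
        tcs[key] = mean_tc / np.maximum(cnt, 1)
    ok = np.logical_and.reduce([np.isfinite(tc) for tc in tcs.values()])
    if ok.sum() < 3:
        raise ValueError("cluster mean time courses have fewer than 3 shared windows")
    tc_mat = np.stack([tcs[k][ok] for k in tcs])  # (K, W_ok)
    tc_mat = tc_mat - tc_mat.mean(axis=1, keepdims=True)
    stc = np.sqrt((tc_mat**2).sum(axis=1))
    if np.any(stc == 0):
        raise ValueError("a cluster mean time course has zero variance")
    vox = twdfc.data[twdfc.traversed][:, ok]
    vals = np.full((len(tcs), vox.shape[0]), np.nan)
    all_defined = np.isfinite(vox).all(axis=1)
    if all_defined.any():  # fast path: correlate fully-defined rows at once
        a = vox[all_defined]
        a = a - a.mean(axis=1, keepdims=True)
        sa = np.sqrt((a**2).sum(axis=1))
        denom = np.where(sa > 0, sa, 1.0)[None, :] * stc[:, None]
        r = (tc_mat @ a.T) / denom
        r[:, sa == 0] = np.nan
        vals[:, all_defined] = r
    for i in np.flatnonzero(~all_defined):  # per-voxel fallback on partial windows
        v = vox[i]
        good = np.isfinite(v)
        if good.sum() < 3:
            continue
        a = v[good] - v[good].mean()
        sa = np.sqrt((a**2).sum())
        if sa == 0:
            continue
        for ki in range(len(tcs)):
            t = tc_mat[ki, good] - tc_mat[ki, good].mean()
            st = np.sqrt((t**2).sum())
            if st > 0:
                vals[ki, i] = (a @ t) / (sa * st)
    out: dict[int, Image3D] = {}
    for ki, key in enumerate(tcs):
        z = np.arctanh(np.clip(vals[ki], -_CLAMP, _CLAMP))
        full = np.full(twdfc.data.shape[:3], np.nan)
        full[twdfc.traversed] = z
        out[key] = Image3D(full, twdfc.affine.copy())
    return out


def winner_takes_all(z_maps: dict[int, np.ndarray] | list[np.ndarray]) -> np.ndarray:
    """Assign each voxel to the cluster with the highest connectivity z.

    Ties go to the lowest cluster index; voxels where every z is <= 0 (or
    undefined) stay background (0).
    """
    if isinstance(z_maps, dict):
        labels = sorted(z_maps)
        stack = np.stack([np.asarray(z_maps[c], dtype=float) for c in labels])
    else:
        labels = list(range(1, len(z_maps) + 1))
        stack = np.stack([np.asarray(m, dtype=float) for m in z_maps])
    if stack.shape[0] < 2:
        raise ValueError("winner-takes-all needs at least 2 maps")
    stack = np.where(np.isfinite(stack), stack, -np.inf)
    best = np.argmax(stack, axis=0)  # first occurrence wins ties -> lowest index
    best_val = np.take_along_axis(stack, best[None], axis=0)[0]
    out = np.zeros(stack.shape[1:], dtype=np.int16)
    assigned = best_val > 0
    out[assigned] = np.asarray(labels, dtype=np.int16)[best[assigned]]
    return out


@dataclass
class PermutationResult:
    """Voxelwise one-sample t with max-statistic FWE-corrected p-values."""

    t_map: np.ndarray
    fwe_p: np.ndarray
    mask: np.ndarray  # FWE p <= alpha
    alpha: float
    n_perm: int


def permutation_onesample(
    maps: list[np.ndarray] | np.ndarray,
    n_perm: int = 5000,
    alpha: float = 0.001,
    seed: int = 0,
    analysis_mask: np.ndarray | None = None,
) -> PermutationResult:
    """One-sample permutation t-test with max-statistic FWE control.

    The null is built by random sign-flipping of the subject maps (the
    unpermuted labelling is included, so p >= 1/(n_perm + 1)); the FWE
    p-value of a voxel is the fraction of null iterations whose maximum
    |t| over the analysis mask reaches that voxel's |t|.  Voxels with zero
    across-subject variance (t undefined) are excluded.
    """
    x = np.stack([np.asarray(m, dtype=float) for m in maps])  # (n, ...)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subject maps")
    flat = x.reshape(n, -1)
    finite = np.isfinite(flat).all(axis=0)
    if analysis_mask is not None:
        finite &= np.asarray(analysis_mask).reshape(-1) > 0
    sd = flat.std(axis=0, ddof=1)
    valid = finite & (sd > 0)
    xv = flat[:, valid]
    ss = (xv**2).sum(axis=0)

    def t_from_mean(mean):
        var = (ss - n * mean**2) / (n - 1)
        var = np.maximum(var, 0.0)
        se = np.sqrt(var / n)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(se > 0, mean / se, 0.0)

    t_obs = t_from_mean(xv.mean(axis=0))
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    max_null = np.empty(n_perm + 1)
    max_null[0] = np.max(np.abs(t_obs)) if t_obs.size else 0.0
    # chunk the sign matrix to bound memory at large n_perm
    chunk = max(1, int(5e7 // max(xv.size, 1)))
    for start in range(0, n_perm, chunk):
        s = signs[start : start + chunk]
        means = (s @ xv) / n
        tperm = t_from_mean(means)
        max_null[1 + start : 1 + start + s.shape[0]] = (
            np.max(np.abs(tperm), axis=1) if tperm.size else 0.0
        )
    pvals = (
        (max_null[None, :] >= np.abs(t_obs)[:, None]).sum(axis=1) / (n_perm + 1)
        if t_obs.size
        else np.empty(0)
    )
    shape = x.shape[1:]
    t_map = np.full(flat.shape[1], np.nan)
    fwe_p = np.full(flat.shape[1], np.nan)
    t_map[valid] = t_obs
    fwe_p[valid] = pvals
    sig = np.zeros(flat.shape[1], dtype=bool)
    sig[valid] = pvals <= alpha
    return PermutationResult(
        t_map.reshape(shape), fwe_p.reshape(shape), sig.reshape(shape), alpha, n_perm
    )


@dataclass
class LateralizationMap:
    """Voxelwise LI with a denominator-guard validity mask."""

    li: np.ndarray
    valid: np.ndarray
    eps: float


def lateralization(zl: np.ndarray, zr: np.ndarray, eps: float = 1e-3) -> LateralizationMap:
    """LI = (Z_left - Z_right) / (Z_left + Z_right), guarded where the
    denominator magnitude is below ``eps`` (LI undefined there)."""
    zl = np.asarray(zl, dtype=float)
    zr = np.asarray(zr, dtype=float)
    if zl.shape != zr.shape:
        raise ValueError("left/right maps must share a grid")
    denom = zl + zr
    valid = np.isfinite(zl) & np.isfinite(zr) & (np.abs(denom) > eps)
    li = np.full(zl.shape, np.nan)
    li[valid] = (zl[valid] - zr[valid]) / denom[valid]
    return LateralizationMap(li, valid, eps)
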