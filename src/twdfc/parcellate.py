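"""Connectivity-based parcellation of a seed ROI from tw-dFC series.

Per subject, every seed (ROI) voxel gets a connectivity fingerprint: the
Fisher-z Pearson correlation of its tw-dFC series with every white-matter
voxel's series (WM series block-downsampled to reduce dimensionality, the
seed kept at native resolution).  Subject-level k-means on the fingerprint
rows yields individual partitions; the group solution is obtained by
consensus clustering — binary voxel-pair co-assignment matrices are averaged
across subjects and k-means is applied to the rows of the group matrix.

k-means uses random data rows as initial centroids, keeping the best of
``n_init`` restarts by within-cluster sum of squares (scikit-learn's
``init="random"`` Lloyd algorithm), deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from .core import TwDfcImage
from .images import Image3D

logger = logging.getLogger(__name__)

__all__ = [
    "Partition",
    "CoAssignmentMatrix",
    "ConnectivityFingerprint",
    "make_wm_mask",
    "extract_series",
    "fingerprint",
    "kmeans_partition",
    "coassignment",
    "consensus",
]

_CLAMP = 1.0 - 1e-7


@dataclass
class Partition:
    """Cluster labels (1..k) over an ordered ROI voxel list."""

    labels: np.ndarray  # (n_voxels,), int, values in 1..k
    k: int
    voxel_list: np.ndarray  # (n_voxels, 3) voxel indices

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.voxel_list = np.asarray(self.voxel_list, dtype=np.int64)
        if self.labels.shape[0] != self.voxel_list.shape[0]:
            raise ValueError("labels and voxel_list length mismatch")
        if self.labels.min(initial=1) < 1 or self.labels.max(initial=1) > self.k:
            raise ValueError("labels must lie in 1..k")

    @property
    def n_voxels(self) -> int:
        return self.labels.shape[0]

    def cluster_mask(self, label: int, shape: tuple[int, int, int]) -> np.ndarray:
        """Binary volume for one cluster."""
        out = np.zeros(shape, dtype=bool)
        sel = self.voxel_list[self.labels == label]
        out[sel[:, 0], sel[:, 1], sel[:, 2]] = True
        return out

    def to_label_volume(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Integer label volume, 0 = background, clusters 1..k."""
        out = np.zeros(shape, dtype=np.int16)
        out[self.voxel_list[:, 0], self.voxel_list[:, 1], self.voxel_list[:, 2]] = (
            self.labels
        )
        return out


@dataclass
class CoAssignmentMatrix:
    """Voxel-pair co-assignment: binary per subject, averaged at group level."""

    q: np.ndarray
    level: str  # "subject" or "group"
    voxel_list: np.ndarray


def make_wm_mask(
    wm_probmaps: list[Image3D],
    roi_masks: list[Image3D],
    dilation_mm: float = 4.0,
    threshold: float = 0.5,
) -> Image3D:
    """Group white-matter analysis mask.

    The subject WM probability maps are averaged and thresholded (>= 50% by
    default); the seed ROIs, dilated by ``dilation_mm``, are subtracted so
    neither the seed signal nor its partial-volume surround leaks into the
    WM feature space.
    """
    if not wm_probmaps:
        raise ValueError("need at least one WM probability map")
    ref = wm_probmaps[0]
    mean_wm = np.mean([np.asarray(m.data, dtype=float) for m in wm_probmaps], axis=0)
    wm = mean_wm >= threshold
    roi = np.zeros(ref.shape, dtype=bool)
    for m in roi_masks:
        roi |= np.asarray(m.data) > 0
    if roi.any() and dilation_mm > 0:
        dist = ndimage.distance_transform_edt(~roi, sampling=ref.voxel_sizes)
        roi = dist <= dilation_mm
    out = wm & ~roi
    if not out.any():
        raise ValueError("WM mask is empty after thresholding and ROI subtraction")
    return ref.like(out)


def _block_downsample(
    data4d: np.ndarray, defined: np.ndarray, factor: int
) -> tuple[np.ndarray, np.ndarray]:
    """Block-mean 4D data over defined entries; returns (data_lo, n_defined_lo)."""
    f = factor
    cx, cy, cz = (s // f * f for s in data4d.shape[:3])
    d = data4d[:cx, :cy, :cz]
    m = defined[:cx, :cy, :cz]
    w = d.shape[3]
    d6 = d.reshape(cx // f, f, cy // f, f, cz // f, f, w)
    m6 = m.reshape(cx // f, f, cy // f, f, cz // f, f, w)
    total = np.where(m6, d6, 0.0).sum(axis=(1, 3, 5))
    cnt = m6.sum(axis=(1, 3, 5))
    with np.errstate(invalid="ignore"):
        lo = np.where(cnt > 0, total / np.maximum(cnt, 1), np.nan)
    return lo, cnt


def extract_series(
    twdfc: TwDfcImage, mask: Image3D, downsample_factor: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Extract per-voxel tw-dFC series under a mask.

    With ``downsample_factor`` > 1 the tw-dFC volume is block-mean
    downsampled by that integer factor before extraction (the WM pathway of
    the pipeline; the seed ROI uses factor 1, i.e. native resolution).
    Returns ``(series, voxel_list)`` where ``series`` is (n_voxels,
    n_windows) and ``voxel_list`` holds (downsampled-grid) voxel indices.
    Only voxels with at least one defined window are returned.
    """
    if not (isinstance(downsample_factor, (int, np.integer)) and downsample_factor >= 1):
        raise ValueError("downsample_factor must be a positive integer")
    defined = ~np.isnan(twdfc.data) & twdfc.traversed[..., None]
    if downsample_factor == 1:
        m = np.asarray(mask.data) > 0
        voxels = np.argwhere(m)
        series = twdfc.data[m]
        has_data = defined[m].any(axis=1)
    else:
        f = int(downsample_factor)
        lo, cnt = _block_downsample(twdfc.data, defined, f)
        m = np.asarray(mask.data) > 0
        cx, cy, cz = (s // f * f for s in m.shape)
        m_lo = (
            m[:cx, :cy, :cz]
            .reshape(cx // f, f, cy // f, f, cz // f, f)
            .any(axis=(1, 3, 5))
        )
        voxels = np.argwhere(m_lo)
        series = lo[m_lo]
        has_data = (cnt[m_lo] > 0).any(axis=1)
    n_dropped = int((~has_data).sum())
    if n_dropped:
        logger.info("dropped %d mask voxel(s) with no defined tw-dFC window", n_dropped)
    return series[has_data], voxels[has_data]


@dataclass
class ConnectivityFingerprint:
    """ROI-voxel x WM-voxel matrix of Fisher-z tw-dFC correlations."""

    matrix: np.ndarray
    roi_voxel_list: np.ndarray
    wm_voxel_list: np.ndarray


def fingerprint(
    roi_series: np.ndarray,
    wm_series: np.ndarray,
    roi_voxel_list: np.ndarray | None = None,
    wm_voxel_list: np.ndarray | None = None,
) -> ConnectivityFingerprint:
    """Fisher-z correlation fingerprint between seed and WM tw-dFC series.

    Windows where any series is undefined are dropped jointly; undefined
    correlations (zero variance) become z = 0 and are counted in the log.
    """
    roi_series = np.asarray(roi_series, dtype=float)
    wm_series = np.asarray(wm_series, dtype=float)
    if roi_series.shape[1] != wm_series.shape[1]:
        raise ValueError("ROI and WM series must share the window axis")
    ok = np.isfinite(roi_series).all(axis=0) & np.isfinite(wm_series).all(axis=0)
    if ok.sum() < 3:
        raise ValueError(f"only {int(ok.sum())} common defined windows (< 3)")
    a = roi_series[:, ok]
    b = wm_series[:, ok]
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt((a**2).sum(axis=1))
    sb = np.sqrt((b**2).sum(axis=1))
    n_degenerate = int((sa == 0).sum() + (sb == 0).sum())
    if n_degenerate:
        logger.info("%d zero-variance series -> fingerprint entries set to 0", n_degenerate)
    denom = np.outer(np.where(sa > 0, sa, 1.0), np.where(sb > 0, sb, 1.0))
    r = (a @ b.T) / denom
    r[sa == 0, :] = 0.0
    r[:, sb == 0] = 0.0
    z = np.arctanh(np.clip(r, -_CLAMP, _CLAMP))
    if roi_voxel_list is None:
        roi_voxel_list = np.arange(roi_series.shape[0])[:, None]
    if wm_voxel_list is None:
        wm_voxel_list = np.arange(wm_series.shape[0])[:, None]
    return ConnectivityFingerprint(z, np.asarray(roi_voxel_list), np.asarray(wm_voxel_list))


def _run_kmeans(x: np.ndarray, k: int, n_init: int, seed: int) -> np.ndarray:
    km = KMeans(
        n_clusters=k,
        init="random",
        n_init=n_init,
        algorithm="lloyd",
        random_state=int(seed) % (2**32 - 1),
    )
    return km.fit_predict(x) + 1


def kmeans_partition(
    fp: ConnectivityFingerprint | np.ndarray,
    k: int,
    n_init: int = 100,
    seed: int = 0,
    voxel_list: np.ndarray | None = None,
) -> Partition:
    """Best-of-``n_init`` k-means partition of fingerprint rows.

    Euclidean distance on the Fisher-z profiles; centroids initialized at k
    randomly chosen data rows; the restart with minimal within-cluster sum
    of squares wins.
    """
    if isinstance(fp, ConnectivityFingerprint):
        x = fp.matrix
        if voxel_list is None:
            voxel_list = fp.roi_voxel_list
    else:
        x = np.asarray(fp, dtype=float)
        if voxel_list is None:
            voxel_list = np.arange(x.shape[0])[:, None]
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds number of data rows {x.shape[0]}")
    if np.unique(x, axis=0).shape[0] < k:
        raise ValueError(f"fewer than k={k} distinct rows")
    labels = _run_kmeans(x, k, n_init, seed)
    return Partition(labels, k, np.asarray(voxel_list))


def coassignment(p: Partition) -> CoAssignmentMatrix:
    """Binary subject-level co-assignment matrix q_ij (1 iff same cluster)."""
    q = (p.labels[:, None] == p.labels[None, :]).astype(float)
    return CoAssignmentMatrix(q, "subject", p.voxel_list)


def consensus(
    partitions: list[Partition],
    k: int,
    n_init: int = 100,
    seed: int = 0,
) -> Partition:
    """Group partition: k-means on the averaged co-assignment matrix rows."""
    if not partitions:
        raise ValueError("no partitions given")
    ref = partitions[0].voxel_list
    for p in partitions[1:]:
        if not np.array_equal(p.voxel_list, ref):
            raise ValueError("partitions are defined over different voxel lists")
    q = group_coassignment(partitions).q
    labels = _run_kmeans(q, k, n_init, seed)
    return Partition(labels, k, ref.copy())


def group_coassignment(partitions: list[Partition]) -> CoAssignmentMatrix:
    """Average of the subjects' binary co-assignment matrices."""
    if not partitions:
        raise ValueError("no partitions given")
    n = partitions[0].n_voxels
    q = np.zeros((n, n), dtype=float)
    for p in partitions:
        q += p.labels[:, None] == p.labels[None, :]
    q /= len(partitions)
    return CoAssignmentMatrix(q, "group", partitions[0].voxel_list)
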