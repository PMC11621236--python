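"""Streamline geometry: voxel traversal, endpoints, track-weighted mapping.

A streamline is an ordered polyline of world-space (mm, RAS) points.  Track-
weighted imaging redistributes information along streamlines: a voxel's value
is an average over the streamlines traversing it of some per-streamline
statistic.  This module provides the traversal bookkeeping (which streamlines
cross which voxels, and where each streamline terminates) that both the
tw-dFC computation and scalar-map track-weighting build on.

Coordinate convention: voxel indices are 0-based; a world point belongs to
the voxel ``floor(A^-1 p + 0.5)`` (voxel-centre cells, half-open boundaries
rounded up), matching common neuroimaging tooling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .images import Image3D

logger = logging.getLogger(__name__)

__all__ = [
    "StreamlineSet",
    "TraversalIndex",
    "point_to_voxel",
    "voxelize_streamline",
    "build_traversal_index",
    "track_weight_scalar_map",
]


class StreamlineSet:
    """A list of streamlines in world (scanner) millimetre coordinates."""

    def __init__(self, streamlines: list[np.ndarray]):
        self.streamlines = [np.asarray(s, dtype=np.float32) for s in streamlines]
        for i, s in enumerate(self.streamlines):
            if s.ndim != 2 or s.shape[1] != 3:
                raise ValueError(f"streamline {i}: expected (N, 3) points, got {s.shape}")

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.streamlines[i]


@dataclass
class TraversalIndex:
    """Per-voxel traversing-streamline sets and per-streamline endpoint voxels.

    ``voxel_to_streamlines[v]`` holds the ids of streamlines whose path
    crosses voxel ``v``; its cardinality is N_v, the track-density weight.
    ``streamline_to_endpoints[i]`` holds the voxels containing streamline
    ``i``'s first and last points.  Streamlines whose endpoints fall outside
    the grid are excluded (counted in ``n_excluded``).
    """

    voxel_to_streamlines: dict[tuple[int, int, int], np.ndarray]
    streamline_to_endpoints: dict[int, tuple[tuple[int, int, int], tuple[int, int, int]]]
    grid_shape: tuple[int, int, int]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    n_excluded: int = 0

    def n_v(self, voxel: tuple[int, int, int]) -> int:
        return len(self.voxel_to_streamlines.get(voxel, ()))

    @property
    def streamline_ids(self) -> list[int]:
        return sorted(self.streamline_to_endpoints)


def point_to_voxel(points: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Map world points (N, 3) to integer voxel indices (round half up)."""
    inv = np.linalg.inv(affine)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    vox = pts @ inv[:3, :3].T + inv[:3, 3]
    return np.floor(vox + 0.5).astype(np.int64)


def _in_grid(vox: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    return np.all((vox >= 0) & (vox < np.asarray(shape)), axis=1)


def _segment_cells(p0: np.ndarray, p1: np.ndarray) -> list[tuple[int, int, int]]:
    """Exact voxel-cell traversal of one segment in continuous voxel
    coordinates (Amanatides-Woo grid walk; cells are centred on integer
    indices with half-open boundaries at half-integers, resolved upward)."""
    v = np.floor(p0 + 0.5).astype(np.int64)
    d = p1 - p0
    cells = [tuple(v)]
    step = np.sign(d).astype(np.int64)
    with np.errstate(divide="ignore"):
        t_delta = np.where(d != 0, 1.0 / np.abs(d), np.inf)
        boundary = v + 0.5 * np.where(step == 0, 1, step)
        t_max = np.where(d != 0, (boundary - p0) / d, np.inf)
    while True:
        axis = int(np.argmin(t_max))
        if t_max[axis] > 1.0:
            break
        v[axis] += step[axis]
        cells.append(tuple(v))
        t_max[axis] += t_delta[axis]
    return cells


def voxelize_streamline(
    streamline: np.ndarray,
    grid: Image3D,
) -> set[tuple[int, int, int]]:
    """Unique voxels whose centre cells are crossed by the polyline.

    Computed by exact grid traversal of each segment (no sampling step to
    tune, no skipped corner clips).  Cells falling outside the grid are
    dropped.
    """
    s = np.asarray(streamline, dtype=float)
    if s.ndim != 2 or s.shape[0] < 2:
        raise ValueError("streamline must have at least 2 points")
    if not np.all(np.isfinite(s)):
        raise ValueError("streamline has non-finite coordinates")
    inv = np.linalg.inv(grid.affine)
    pts = s @ inv[:3, :3].T + inv[:3, 3]
    cells: set[tuple[int, int, int]] = set()
    for a, b in zip(pts[:-1], pts[1:]):
        cells.update(_segment_cells(a, b))
    shape = grid.shape
    return {
        c
        for c in cells
        if 0 <= c[0] < shape[0] and 0 <= c[1] < shape[1] and 0 <= c[2] < shape[2]
    }


def build_traversal_index(
    ss: StreamlineSet,
    grid: Image3D,
) -> TraversalIndex:
    """Index voxel traversal and endpoint voxels for a streamline set.

    Streamlines with either terminal point outside the grid are excluded
    from the index entirely; the count is logged and recorded.
    """
    if len(ss) == 0:
        raise ValueError("streamline set is empty")
    voxel_to: dict[tuple[int, int, int], list[int]] = {}
    endpoints: dict[int, tuple[tuple[int, int, int], tuple[int, int, int]]] = {}
    n_excluded = 0
    shape = grid.shape
    for i, s in enumerate(ss):
        epts = point_to_voxel(np.asarray([s[0], s[-1]], dtype=float), grid.affine)
        if not np.all(_in_grid(epts, shape)):
            n_excluded += 1
            continue
        endpoints[i] = (tuple(epts[0]), tuple(epts[1]))
        for v in voxelize_streamline(s, grid):
            voxel_to.setdefault(v, []).append(i)
    if n_excluded:
        logger.info("excluded %d streamline(s) with endpoints outside the grid", n_excluded)
    packed = {v: np.asarray(ids, dtype=np.int64) for v, ids in voxel_to.items()}
    return TraversalIndex(packed, endpoints, shape, grid.affine.copy(), n_excluded)


def track_weight_scalar_map(
    ss: StreamlineSet,
    scalar: Image3D,
    index: TraversalIndex | None = None,
) -> Image3D:
    """Track-weight a scalar map: redistribute its values along streamlines.

    Per streamline, the statistic is the mean of the scalar sampled at the
    streamline's own points (nearest-voxel lookup; out-of-grid and NaN
    samples are skipped).  Per voxel, the output is the mean of that
    statistic over all traversing streamlines; voxels traversed by no
    streamline stay 0.  Streamlines with no valid sample contribute nothing.
    """
    if index is None:
        index = build_traversal_index(ss, scalar)
    per_streamline: dict[int, float] = {}
    n_empty = 0
    for i in index.streamline_ids:
        s = ss[i]
        vox = point_to_voxel(np.asarray(s, dtype=float), scalar.affine)
        ok = _in_grid(vox, scalar.shape)
        vals = scalar.data[vox[ok, 0], vox[ok, 1], vox[ok, 2]].astype(float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            n_empty += 1
            continue
        per_streamline[i] = float(vals.mean())
    if n_empty:
        logger.info("%d streamline(s) had no valid scalar samples", n_empty)
    out = np.zeros(scalar.shape, dtype=float)
    for v, ids in index.voxel_to_streamlines.items():
        vals = [per_streamline[i] for i in ids if i in per_streamline]
        if vals:
            out[v] = float(np.mean(vals))
    return scalar.like(out)
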