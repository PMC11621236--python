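"""Track-weighted dynamic functional connectivity (tw-dFC).

The BOLD series is segmented into partially overlapping rectangular sliding
windows.  For each streamline i, FC_i(t) is the Pearson correlation of the
BOLD signals at its two endpoint voxels within window t.  The tw-dFC value
of a white-matter voxel v at window t is the average of FC_i(t) over the
N_v streamlines traversing v:

    tw-dFC(v, t) = (1 / N_v) * sum_i FC_i(t)

so dynamic-connectivity information at the endpoints is propagated along
the streamlines connecting them: all voxels traversed by only streamline i
carry exactly the series FC_i.

Windows where an endpoint series has zero variance yield an undefined
correlation; undefined contributions are excluded from the voxel average
(NaN in the output), never treated as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .images import Image3D, Image4D
from .tractmap import TraversalIndex

__all__ = [
    "WindowSpec",
    "StreamlineFcSeries",
    "TwDfcImage",
    "make_windows",
    "windowed_endpoint_fc",
    "windowed_fc_matrix",
    "compute_twdfc",
]


@dataclass(frozen=True)
class WindowSpec:
    """Rectangular sliding-window parameters, in timepoints."""

    length_tp: int
    stride_tp: int = 1

    def __post_init__(self) -> None:
        if self.length_tp < 2:
            raise ValueError("window length must be at least 2 timepoints")
        if self.stride_tp < 1:
            raise ValueError("window stride must be at least 1 timepoint")


@dataclass
class StreamlineFcSeries:
    """Per-window endpoint Pearson correlation for one streamline."""

    values: np.ndarray  # (n_windows,), NaN where undefined
    window_starts: np.ndarray  # (n_windows,)


@dataclass
class TwDfcImage:
    """4D tw-dFC volume over (voxel, window).

    ``data[x, y, z, t]`` is the mean endpoint FC of the streamlines
    traversing the voxel in window t.  Voxels traversed by no streamline
    are 0 with ``traversed`` False; traversed voxel-windows with no defined
    correlation are NaN.
    """

    data: np.ndarray
    traversed: np.ndarray
    affine: np.ndarray
    spec: WindowSpec
    window_starts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def n_windows(self) -> int:
        return self.data.shape[3]

    def series(self, voxel: tuple[int, int, int]) -> np.ndarray:
        return self.data[voxel[0], voxel[1], voxel[2], :]

    @classmethod
    def from_image4d(cls, img: Image4D, spec: WindowSpec) -> "TwDfcImage":
        """Rebuild from a stored 4D volume (background voxels are all-zero;
        undefined voxel-windows are NaN)."""
        data = np.asarray(img.data, dtype=np.float64)
        traversed = ~np.all(data == 0, axis=3)
        starts = np.arange(data.shape[3] * spec.stride_tp, step=spec.stride_tp)
        return cls(data, traversed, np.asarray(img.affine), spec, starts)


def make_windows(n_timepoints: int, spec: WindowSpec) -> list[tuple[int, int]]:
    """Half-open [start, start+length) window intervals fully inside the series."""
    if spec.length_tp > n_timepoints:
        raise ValueError(
            f"window length {spec.length_tp} exceeds series length {n_timepoints}"
        )
    n_win = (n_timepoints - spec.length_tp) // spec.stride_tp + 1
    return [
        (i * spec.stride_tp, i * spec.stride_tp + spec.length_tp) for i in range(n_win)
    ]


def windowed_fc_matrix(
    a: np.ndarray, b: np.ndarray, n_timepoints: int, spec: WindowSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Windowed Pearson correlation for paired series, vectorized.

    ``a`` and ``b`` are (S, T) arrays of paired endpoint series.  Returns
    (S, W) correlations (NaN where either window has zero variance) and the
    (W,) window start indices.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    windows = make_windows(n_timepoints, spec)
    starts = np.asarray([w[0] for w in windows], dtype=np.int64)
    L = spec.length_tp
    wa = np.lib.stride_tricks.sliding_window_view(a, L, axis=-1)[:, starts, :]
    wb = np.lib.stride_tricks.sliding_window_view(b, L, axis=-1)[:, starts, :]
    ca = wa - wa.mean(axis=-1, keepdims=True)
    cb = wb - wb.mean(axis=-1, keepdims=True)
    va = np.einsum("swl,swl->sw", ca, ca)
    vb = np.einsum("swl,swl->sw", cb, cb)
    cov = np.einsum("swl,swl->sw", ca, cb)
    denom = np.sqrt(va * vb)
    with np.errstate(invalid="ignore", divide="ignore"):
        fc = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), np.nan)
    return fc, starts


def windowed_endpoint_fc(
    bold: Image4D,
    endpoints: tuple[tuple[int, int, int], tuple[int, int, int]],
    spec: WindowSpec,
) -> StreamlineFcSeries:
    """Sliding-window Pearson correlation between two endpoint voxels' BOLD."""
    (ax, ay, az), (bx, by, bz) = endpoints
    shape = bold.shape[:3]
    for v in endpoints:
        if any(c < 0 or c >= n for c, n in zip(v, shape)):
            raise ValueError(f"endpoint voxel {v} outside grid {shape}")
    a = bold.data[ax, ay, az, :][None, :]
    b = bold.data[bx, by, bz, :][None, :]
    fc, starts = windowed_fc_matrix(a, b, bold.n_timepoints, spec)
    return StreamlineFcSeries(fc[0], starts)


def compute_twdfc(
    bold: Image4D, index: TraversalIndex, spec: WindowSpec
) -> TwDfcImage:
    """Project windowed endpoint FC onto the traversed white-matter voxels."""
    if not index.streamline_to_endpoints:
        raise ValueError("traversal index contains no streamlines")
    if tuple(index.grid_shape) != tuple(bold.shape[:3]):
        raise ValueError(
            f"index grid {index.grid_shape} does not match BOLD grid {bold.shape[:3]}"
        )
    ids = index.streamline_ids
    row_of = {sid: r for r, sid in enumerate(ids)}
    epts = np.asarray(
        [index.streamline_to_endpoints[sid] for sid in ids], dtype=np.int64
    )  # (S, 2, 3)
    a = bold.data[epts[:, 0, 0], epts[:, 0, 1], epts[:, 0, 2], :]
    b = bold.data[epts[:, 1, 0], epts[:, 1, 1], epts[:, 1, 2], :]
    fc, starts = windowed_fc_matrix(a, b, bold.n_timepoints, spec)
    n_win = fc.shape[1]
    out = np.zeros(bold.shape[:3] + (n_win,), dtype=np.float64)
    traversed = np.zeros(bold.shape[:3], dtype=bool)
    # group voxels and accumulate sums/counts in one vectorized pass;
    # single-streamline voxels copy the FC row so propagation is bit-exact
    vox_keys: list[tuple[int, int, int]] = []
    flat_rows: list[int] = []
    flat_vox: list[int] = []
    for v, sids in index.voxel_to_streamlines.items():
        rows = [row_of[sid] for sid in sids if sid in row_of]
        if not rows:
            continue
        traversed[v] = True
        if len(rows) == 1:
            out[v] = fc[rows[0]]
        else:
            vi = len(vox_keys)
            vox_keys.append(v)
            flat_rows.extend(rows)
            flat_vox.extend([vi] * len(rows))
    if vox_keys:
        rows_a = np.asarray(flat_rows)
        vox_a = np.asarray(flat_vox)
        block = fc[rows_a]  # (n_pairs, W)
        valid = ~np.isnan(block)
        n_multi = len(vox_keys)
        sums = np.zeros((n_multi, n_win))
        cnts = np.zeros((n_multi, n_win))
        np.add.at(sums, vox_a, np.where(valid, block, 0.0))
        np.add.at(cnts, vox_a, valid.astype(float))
        means = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
        vk = np.asarray(vox_keys)
        out[vk[:, 0], vk[:, 1], vk[:, 2]] = means
    return TwDfcImage(out, traversed, bold.affine.copy(), spec, starts)
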