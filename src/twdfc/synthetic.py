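"""Multi-subject synthetic scenes with planted tw-dFC structure.

The generator emulates the data model the analysis assumes, at desk scale:

* a mirrored pair of seed ROIs (left/right "pulvinar"), each partitioned
  into ``k_true`` planted connectivity clusters;
* one ipsilateral target territory per cluster per hemisphere, the right
  territories being exact x-reflections of the left ones, so every voxel
  has an exact homotopic counterpart;
* streamline bundles from every seed-cluster voxel to its ipsilateral
  target territory (piecewise-linear, ~1-voxel steps, jittered control
  points, endpoints snapped inside their regions); the right-hemisphere
  streamlines are bit-exact mirror images of the left ones;
* BOLD in which the coupling between a seed cluster's latent signal and its
  target territory is modulated sinusoidally in time,

      r_c(t) = coupling_amplitude * (1 + sin(2*pi*t/P_c + phi_c)) / 2

  with a distinct period P_c and phase phi_c per cluster, plus i.i.d.
  Gaussian voxel noise.

Cluster coupling waveforms are frequency-coded: cluster c completes an
integer number of cycles (2, 3, 4, ...) over the span covered by the
window centres of the planned sliding window, so the waveforms of
different clusters are mutually orthogonal and a voxel's windowed-FC
series identifies its cluster unambiguously.  The two hemispheres of a
cluster share the identical deterministic waveform but independent
latent signals: under equal coupling amplitudes the left and right
systems are therefore exactly exchangeable — any functional of one
system has the same distribution as its mirrored counterpart — giving
the lateralization index an exact null, while the
``right_coupling_scale`` knob yields detectable lateralization.  A
consequence of the shared waveform is that each cluster's connectivity
profile is genuinely bilateral (a seed cluster correlates with both its
own and the homotopic contralateral network), as in real data.

Everything is deterministic for a fixed ``seed``: two builds from the same
config are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .images import Image3D, Image4D
from .parcellate import Partition
from .tractmap import StreamlineSet, TraversalIndex, build_traversal_index

__all__ = ["SceneConfig", "SyntheticScene", "build_scene", "smooth_bold"]

# (y, z) anchor corners for target territories; supports k_true up to 8
_TARGET_ANCHORS = [
    (2, 2),
    (16, 16),
    (2, 16),
    (16, 2),
    (2, 9),
    (16, 9),
    (9, 2),
    (9, 16),
]


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a synthetic scene (defaults define the study conditions)."""

    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 2.0
    tr_s: float = 1.0
    n_timepoints: int = 440
    n_subjects: int = 20
    k_true: int = 4
    n_streamlines_per_cluster: int = 150
    coupling_amplitude: float = 0.9
    coupling_period_s: float = 200.0
    noise_sd: float = 0.3
    right_coupling_scale: float = 1.0
    planned_window_tp: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_true < 2:
            raise ValueError("k_true must be at least 2")
        if self.k_true > len(_TARGET_ANCHORS):
            raise ValueError(f"k_true > {len(_TARGET_ANCHORS)} target territories available")
        if not 0.0 <= self.coupling_amplitude <= 1.0:
            raise ValueError("coupling_amplitude must lie in [0, 1]")
        if self.coupling_amplitude * self.right_coupling_scale > 1.0:
            raise ValueError("right-scaled coupling amplitude exceeds 1")
        if self.n_timepoints < 2 * self.planned_window_tp:
            raise ValueError("n_timepoints must be at least twice the planned window")
        if min(self.grid_shape) < 16:
            raise ValueError("grid must be at least 16 voxels per axis")


@dataclass
class SyntheticScene:
    """A generated scene: BOLD, masks, streamlines, and the planted truth."""

    config: SceneConfig
    bold_per_subject: list[Image4D]
    roi_left: Image3D
    roi_right: Image3D
    wm_mask: Image3D
    atlas_labels: Image3D
    streamlines: StreamlineSet
    streamline_cluster: np.ndarray  # (S,) planted cluster of each streamline
    streamline_hemi: np.ndarray  # (S,) "L" or "R"
    truth_left: Partition
    truth_right: Partition
    target_regions: dict[int, Image3D]  # per cluster, both hemispheres merged
    target_left: dict[int, Image3D]
    target_right: dict[int, Image3D]
    traversal: TraversalIndex
    r_left: np.ndarray = field(default_factory=lambda: np.empty(0))  # (k, T)
    r_right: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def affine(self) -> np.ndarray:
        return self.roi_left.affine


def _scaled(n: int, lo24: int, hi24: int) -> tuple[int, int]:
    """Scale an inclusive [lo, hi] voxel range defined on a 24-grid to size n."""
    lo = int(round(n * lo24 / 24))
    hi = int(round(n * (hi24 + 1) / 24)) - 1
    return lo, max(hi, lo)


def _block_voxels(xr, yr, zr) -> np.ndarray:
    xs, ys, zs = (np.arange(r[0], r[1] + 1) for r in (xr, yr, zr))
    g = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)
    return g.reshape(-1, 3)


def _chunk_labels(order: np.ndarray, k: int) -> np.ndarray:
    """Near-equal contiguous chunks along a voxel ordering -> labels 1..k."""
    n = order.shape[0]
    bounds = np.linspace(0, n, k + 1).round().astype(int)
    labels = np.empty(n, dtype=np.int64)
    for c in range(k):
        labels[bounds[c] : bounds[c + 1]] = c + 1
    out = np.empty(n, dtype=np.int64)
    out[order] = labels
    return out


def build_scene(cfg: SceneConfig) -> SyntheticScene:
    """Generate a complete multi-subject scene from a configuration."""
    nx, ny, nz = cfg.grid_shape
    vs = cfg.voxel_size_mm
    affine = np.diag([vs, vs, vs, 1.0])
    affine[:3, 3] = -vs * np.asarray(cfg.grid_shape) / 2.0
    rng = np.random.default_rng(cfg.seed)

    # --- geometry -------------------------------------------------------
    roi_x = _scaled(nx, 4, 7)
    roi_y = _scaled(ny, 8, 13)
    roi_z = _scaled(nz, 8, 13)
    left_vox = _block_voxels(roi_x, roi_y, roi_z)
    right_vox = left_vox.copy()
    right_vox[:, 0] = nx - 1 - right_vox[:, 0]

    # one ipsilateral target territory per cluster per hemisphere; the right
    # territories are exact x-reflections of the left ones
    tgt_x = _scaled(nx, 9, 11)
    target_lvox: dict[int, np.ndarray] = {}
    target_rvox: dict[int, np.ndarray] = {}
    for c in range(1, cfg.k_true + 1):
        ay, az = _TARGET_ANCHORS[c - 1]
        yr = _scaled(ny, ay, ay + 5)
        zr = _scaled(nz, az, az + 5)
        target_lvox[c] = _block_voxels(tgt_x, yr, zr)
        tr = target_lvox[c].copy()
        tr[:, 0] = nx - 1 - tr[:, 0]
        target_rvox[c] = tr

    occupied = np.zeros(cfg.grid_shape, dtype=np.int16)
    for region in [left_vox, right_vox, *target_lvox.values(), *target_rvox.values()]:
        occupied[region[:, 0], region[:, 1], region[:, 2]] += 1
    if occupied.max() > 1:
        raise ValueError("scene geometry is inconsistent: regions overlap")

    # planted clusters: contiguous chunks of the (y, z, x)-sorted seed voxels
    order_yzx = np.lexsort((left_vox[:, 0], left_vox[:, 2], left_vox[:, 1]))
    truth_labels = _chunk_labels(order_yzx, cfg.k_true)
    truth_left = Partition(truth_labels, cfg.k_true, left_vox)
    truth_right = Partition(truth_labels.copy(), cfg.k_true, right_vox)

    # synthetic "atlas nuclei": a second partition chunked along another axis
    order_zyx = np.lexsort((left_vox[:, 0], left_vox[:, 1], left_vox[:, 2]))
    atlas = np.zeros(cfg.grid_shape, dtype=np.int16)
    nuclei = _chunk_labels(order_zyx, cfg.k_true)
    atlas[left_vox[:, 0], left_vox[:, 1], left_vox[:, 2]] = nuclei
    atlas[right_vox[:, 0], right_vox[:, 1], right_vox[:, 2]] = nuclei

    # --- streamlines ----------------------------------------------------
    def world(v):
        return np.asarray(v, dtype=float) * vs + affine[:3, 3]

    def polyline(waypoints: list[np.ndarray], jitter_sd: float) -> np.ndarray:
        """~1-voxel-step piecewise-linear curve through waypoints, jittered
        interior control points (endpoints untouched)."""
        pts = [waypoints[0][None]]
        for a, b in zip(waypoints[:-1], waypoints[1:]):
            n = max(1, int(np.ceil(np.linalg.norm(b - a) / vs)))
            ts = np.arange(1, n + 1)[:, None] / n
            pts.append(a[None] + ts * (b - a)[None])
        out = np.vstack(pts)
        if out.shape[0] > 2:
            out[1:-1] += rng.normal(0.0, jitter_sd, (out.shape[0] - 2, 3))
        return out

    # Left streamlines leave the seed along +x within their own (y, z)
    # column — so a seed voxel is only traversed by its own cluster's
    # bundle — then bridge to an approach point on the target face nearest
    # the seed and descend into the territory along a per-target-voxel
    # "tail".  Right streamlines are exact x-reflections of the left ones,
    # giving the two hemispheres bit-identical mirrored geometry (exact
    # homotopy), which is what makes the lateralization null exchangeable.
    exit_x_left = (roi_x[1] + 1.5) * vs + affine[0, 3]
    left_lines: list[np.ndarray] = []
    s_cluster_half: list[int] = []
    for c in range(1, cfg.k_true + 1):
        src = truth_left.voxel_list[truth_left.labels == c]
        tgt = target_lvox[c]
        y_lo, y_hi = tgt[:, 1].min(), tgt[:, 1].max()
        face_y = y_hi + 1 if y_hi < ny // 2 else y_lo - 1  # face toward the seed
        n_t = tgt.shape[0]
        tails = []
        for j in range(n_t):
            vj = tgt[j]
            ap = world(np.array([vj[0], face_y, vj[2]], dtype=float))
            p1 = world(vj) + rng.uniform(-0.4, 0.4, 3) * vs
            tails.append(polyline([ap, p1], jitter_sd=0.2).astype(np.float32))
        for i in range(cfg.n_streamlines_per_cluster):
            v0 = src[i % src.shape[0]]
            tail = tails[i % n_t]
            p0 = world(v0) + rng.uniform(-0.4, 0.4, 3) * vs
            gate = np.array([exit_x_left, p0[1], p0[2]])
            bridge = polyline([p0, gate, tail[0].astype(float)], jitter_sd=0.3)
            left_lines.append(np.vstack([bridge.astype(np.float32), tail[1:]]))
            s_cluster_half.append(c)

    streamlines = list(left_lines)
    s_cluster = list(s_cluster_half)
    s_hemi = ["L"] * len(left_lines)
    centre_x = affine[0, 3] + vs * (nx - 1) / 2.0  # world x of the grid centre
    for pts, c in zip(left_lines, s_cluster_half):
        m = pts.copy()
        m[:, 0] = 2.0 * np.float32(centre_x) - m[:, 0]
        streamlines.append(m)
        s_cluster.append(c)
        s_hemi.append("R")
    ss = StreamlineSet(streamlines)
    grid = Image3D(np.zeros(cfg.grid_shape, dtype=np.int8), affine)
    traversal = build_traversal_index(ss, grid)

    # WM probability: traversed voxels plus target territories
    wm = np.zeros(cfg.grid_shape, dtype=np.float32)
    for v in traversal.voxel_to_streamlines:
        wm[v] = 1.0
    for tv in list(target_lvox.values()) + list(target_rvox.values()):
        wm[tv[:, 0], tv[:, 1], tv[:, 2]] = 1.0

    # --- planted coupling profiles --------------------------------------
    # cluster c runs m_1 + c - 1 full cycles over the window-centre span of
    # the planned window, where m_1 = cycles of the configured base period:
    # distinct integer cycle counts make the cluster waveforms orthogonal
    t_s = np.arange(cfg.n_timepoints) * cfg.tr_s
    span_s = (cfg.n_timepoints - cfg.planned_window_tp) * cfg.tr_s
    m1 = max(1, round(span_s / cfg.coupling_period_s))
    r_left = np.empty((cfg.k_true, cfg.n_timepoints))
    r_right = np.empty((cfg.k_true, cfg.n_timepoints))
    for c in range(cfg.k_true):
        omega = 2.0 * np.pi * (m1 + c) / span_s
        phi = 2.0 * np.pi * c / cfg.k_true
        r_left[c] = cfg.coupling_amplitude * 0.5 * (1.0 + np.sin(omega * t_s + phi))
        r_right[c] = cfg.right_coupling_scale * r_left[c]
    r_left = np.clip(r_left, 0.0, 0.999)
    r_right = np.clip(r_right, 0.0, 0.999)

    # --- BOLD -----------------------------------------------------------
    # the two hemispheric systems are disjoint and statistically
    # independent; each cluster couples its seed latent to its ipsilateral
    # target territory with the time-varying loading r(t)
    bold_list: list[Image4D] = []
    T = cfg.n_timepoints
    for _s in range(cfg.n_subjects):
        bold = rng.normal(0.0, 1.0, cfg.grid_shape + (T,)).astype(np.float32)
        bold *= np.float32(cfg.noise_sd)
        for c in range(cfg.k_true):
            for truth, targets, r in (
                (truth_left, target_lvox, r_left[c]),
                (truth_right, target_rvox, r_right[c]),
            ):
                x = rng.normal(0.0, 1.0, T)
                eta = rng.normal(0.0, 1.0, T)
                g = np.sqrt(np.clip(1.0 - r**2, 0.0025, 1.0))
                u = r * x + g * eta
                sv = truth.voxel_list[truth.labels == c + 1]
                bold[sv[:, 0], sv[:, 1], sv[:, 2], :] += x.astype(np.float32)
                tv = targets[c + 1]
                bold[tv[:, 0], tv[:, 1], tv[:, 2], :] += u.astype(np.float32)
        bold_list.append(Image4D(bold, affine.copy(), tr_s=cfg.tr_s))

    def mask_img(vox: np.ndarray) -> Image3D:
        m = np.zeros(cfg.grid_shape, dtype=np.uint8)
        m[vox[:, 0], vox[:, 1], vox[:, 2]] = 1
        return Image3D(m, affine.copy())

    return SyntheticScene(
        config=cfg,
        bold_per_subject=bold_list,
        roi_left=mask_img(left_vox),
        roi_right=mask_img(right_vox),
        wm_mask=Image3D(wm, affine.copy()),
        atlas_labels=Image3D(atlas, affine.copy()),
        streamlines=ss,
        streamline_cluster=np.asarray(s_cluster),
        streamline_hemi=np.asarray(s_hemi),
        truth_left=truth_left,
        truth_right=truth_right,
        target_regions={
            c: mask_img(np.vstack([target_lvox[c], target_rvox[c]]))
            for c in target_lvox
        },
        target_left={c: mask_img(v) for c, v in target_lvox.items()},
        target_right={c: mask_img(v) for c, v in target_rvox.items()},
        traversal=traversal,
        r_left=r_left,
        r_right=r_right,
    )


def smooth_bold(img: Image4D, fwhm_mm: float) -> Image4D:
    """Spatial Gaussian smoothing of each BOLD frame; fwhm 0 is the identity."""
    if fwhm_mm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm_mm == 0:
        return img.like(img.data.copy())
    sigma_mm = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_vox = sigma_mm / img.voxel_sizes
    out = np.empty_like(np.asarray(img.data, dtype=np.float32))
    data = np.asarray(img.data, dtype=np.float32)
    for t in range(img.n_timepoints):
        out[..., t] = ndimage.gaussian_filter(data[..., t], sigma=sigma_vox)
    return img.like(out)


def scene_config_dict(cfg: SceneConfig) -> dict:
    """JSON-serializable view of a SceneConfig."""
    d = asdict(cfg)
    d["grid_shape"] = list(cfg.grid_shape)
    return d
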