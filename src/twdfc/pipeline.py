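"""Pipeline orchestration.

Two layers:

* in-memory helpers operating on a :class:`~twdfc.synthetic.SyntheticScene`
  (or equivalent arrays) — these are the building blocks the tests and the
  acceptance analyses use;
* :func:`run_pipeline`, a file-based driver for the CLI that reads NIfTI /
  TCK inputs, executes smoothing -> tw-dFC -> parcellation (per hemisphere)
  -> validity -> characterization, and writes outputs plus a manifest with
  per-stage checksums (bit-reproducible for a fixed configuration).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as tio
from .characterize import (
    PermutationResult,
    cluster_timecourse_maps,
    lateralization,
    overlap_table,
    permutation_onesample,
    winner_takes_all,
)
from .core import TwDfcImage, WindowSpec, compute_twdfc
from .images import Image3D, Image4D
from .parcellate import (
    Partition,
    consensus,
    extract_series,
    fingerprint,
    kmeans_partition,
    make_wm_mask,
)
from .synthetic import SceneConfig, SyntheticScene, build_scene, scene_config_dict, smooth_bold
from .tractmap import TraversalIndex, build_traversal_index
from .validity import dice, silhouette, splithalf_nvi

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "subject_twdfc",
    "subject_fingerprint",
    "parcellate_subjects",
    "subject_cluster_zmaps",
    "preferential_analysis",
    "lateralization_analysis",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# in-memory building blocks


def subject_twdfc(
    bold: Image4D, traversal: TraversalIndex, window: WindowSpec, fwhm_mm: float = 0.0
) -> TwDfcImage:
    """Smooth (optionally) and compute the tw-dFC volume for one subject."""
    if fwhm_mm > 0:
        bold = smooth_bold(bold, fwhm_mm)
    return compute_twdfc(bold, traversal, window)


def subject_fingerprint(
    twdfc: TwDfcImage,
    roi_mask: Image3D,
    wm_mask: Image3D,
    downsample_factor: int = 2,
):
    """ROI x WM Fisher-z fingerprint for one subject's tw-dFC volume."""
    roi_series, roi_vox = extract_series(twdfc, roi_mask, 1)
    wm_series, wm_vox = extract_series(twdfc, wm_mask, downsample_factor)
    return fingerprint(roi_series, wm_series, roi_vox, wm_vox)


@dataclass
class ParcellationResult:
    subject_partitions: list[Partition]
    group: Partition
    fingerprints: list


def parcellate_subjects(
    scene: SyntheticScene,
    window: WindowSpec,
    k: int,
    seed: int,
    hemi: str = "L",
    n_init: int = 100,
    dilation_mm: float = 4.0,
    downsample_factor: int = 2,
    fwhm_mm: float = 0.0,
    subjects: list[int] | None = None,
) -> ParcellationResult:
    """Full subject-level + consensus parcellation of one hemisphere's seed."""
    roi = scene.roi_left if hemi == "L" else scene.roi_right
    wm = make_wm_mask([scene.wm_mask], [scene.roi_left, scene.roi_right], dilation_mm)
    rng = np.random.default_rng(seed)
    idx = range(len(scene.bold_per_subject)) if subjects is None else subjects
    partitions: list[Partition] = []
    fps = []
    for s in idx:
        tw = subject_twdfc(scene.bold_per_subject[s], scene.traversal, window, fwhm_mm)
        fp = subject_fingerprint(tw, roi, wm, downsample_factor)
        fps.append(fp)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        partitions.append(kmeans_partition(fp, k, n_init=n_init, seed=sub_seed))
    group_seed = int(rng.integers(0, 2**31 - 1))
    group = consensus(partitions, k, n_init=n_init, seed=group_seed)
    return ParcellationResult(partitions, group, fps)


def subject_cluster_zmaps(
    scene: SyntheticScene,
    window: WindowSpec,
    group: Partition,
    subjects: list[int] | None = None,
    fwhm_mm: float = 0.0,
) -> list[dict[int, np.ndarray]]:
    """Per-subject Fisher-z whole-brain connectivity maps of each cluster."""
    shape = scene.roi_left.shape
    idx = range(len(scene.bold_per_subject)) if subjects is None else subjects
    masks = {c: group.cluster_mask(c, shape) for c in range(1, group.k + 1)}
    out: list[dict[int, np.ndarray]] = []
    for s in idx:
        tw = subject_twdfc(scene.bold_per_subject[s], scene.traversal, window, fwhm_mm)
        out.append({c: m.data for c, m in cluster_timecourse_maps(tw, masks).items()})
    return out


def subject_cluster_zmaps_bilateral(
    scene: SyntheticScene,
    window: WindowSpec,
    group_left: Partition,
    group_right: Partition,
    subjects: list[int] | None = None,
    fwhm_mm: float = 0.0,
) -> tuple[list[dict[int, np.ndarray]], list[dict[int, np.ndarray]]]:
    """Per-subject cluster z maps for both seeds from one tw-dFC pass each."""
    shape = scene.roi_left.shape
    idx = range(len(scene.bold_per_subject)) if subjects is None else subjects
    masks = {("L", c): group_left.cluster_mask(c, shape) for c in range(1, group_left.k + 1)}
    masks |= {("R", c): group_right.cluster_mask(c, shape) for c in range(1, group_right.k + 1)}
    out_l: list[dict[int, np.ndarray]] = []
    out_r: list[dict[int, np.ndarray]] = []
    for s in idx:
        tw = subject_twdfc(scene.bold_per_subject[s], scene.traversal, window, fwhm_mm)
        res = cluster_timecourse_maps(tw, masks)
        out_l.append({c: res[("L", c)].data for c in range(1, group_left.k + 1)})
        out_r.append({c: res[("R", c)].data for c in range(1, group_right.k + 1)})
    return out_l, out_r


@dataclass
class PreferentialResult:
    wta_labels: np.ndarray
    group_mean_z: dict[int, np.ndarray]
    per_cluster: dict[int, PermutationResult]


def preferential_analysis(
    subject_zmaps: list[dict[int, np.ndarray]],
    n_perm: int = 5000,
    alpha: float = 0.001,
    seed: int = 0,
) -> PreferentialResult:
    """Winner-takes-all preferential maps with permutation FWE inference.

    The group-mean z map per cluster defines the winner-takes-all
    parcellation of the traversed white matter; subject z maps masked to
    each cluster's territory undergo a one-sample sign-flip permutation
    t-test with max-statistic FWE correction.
    """
    clusters = sorted(subject_zmaps[0])
    mean_z = {}
    for c in clusters:
        stack = np.stack([m[c] for m in subject_zmaps])
        good = np.isfinite(stack)
        cnt = good.sum(axis=0)
        mean_z[c] = np.where(
            cnt > 0, np.where(good, stack, 0.0).sum(axis=0) / np.maximum(cnt, 1), np.nan
        )
    wta = winner_takes_all(mean_z)
    rng = np.random.default_rng(seed)
    results: dict[int, PermutationResult] = {}
    for c in clusters:
        mask_c = wta == c
        maps = [np.where(mask_c, m[c], np.nan) for m in subject_zmaps]
        results[c] = permutation_onesample(
            maps,
            n_perm=n_perm,
            alpha=alpha,
            seed=int(rng.integers(0, 2**31 - 1)),
            analysis_mask=mask_c,
        )
    return PreferentialResult(wta, mean_z, results)


@dataclass
class LateralizationResult:
    pairing: list[tuple[int, int, float]]
    per_pair: dict[tuple[int, int], PermutationResult]


def lateralization_analysis(
    left_pref: PreferentialResult,
    right_pref: PreferentialResult,
    left_zmaps: list[dict[int, np.ndarray]],
    right_zmaps: list[dict[int, np.ndarray]],
    n_perm: int = 5000,
    alpha: float = 0.001,
    seed: int = 0,
    eps: float = 1e-3,
    homotopic_flip: bool = True,
) -> LateralizationResult:
    """Voxelwise LI inference for corresponding left/right clusters.

    Homotopic voxel correspondence: with ``homotopic_flip`` the right-seed
    maps are reflected along the first (left-right) axis before comparison,
    so Z_left(v) is set against Z_right at the mirror voxel (in a symmetric
    standard space the two conventions coincide up to that reflection).
    Left and right clusters are paired greedily by the Dice overlap of
    their (reflected) winner-takes-all territories.  LI is evaluated where
    BOTH hemispheres' group preferential maps are FWE-significant — i.e.
    on white matter with established connectivity in each hemisphere —
    since outside that support the ratio degenerates to ±1 wherever one
    map is near zero.  Per subject and pair, the LI maps then undergo the
    one-sample sign-flip permutation test.
    """

    def flip(a: np.ndarray) -> np.ndarray:
        return np.flip(a, axis=0) if homotopic_flip else a

    kl = sorted(left_pref.per_cluster)
    kr = sorted(right_pref.per_cluster)
    pairs = []
    for cl in kl:
        for cr in kr:
            pairs.append(
                (dice(left_pref.wta_labels == cl, flip(right_pref.wta_labels == cr)), cl, cr)
            )
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_l: set[int] = set()
    used_r: set[int] = set()
    pairing: list[tuple[int, int, float]] = []
    for d, cl, cr in pairs:
        if cl in used_l or cr in used_r:
            continue
        used_l.add(cl)
        used_r.add(cr)
        pairing.append((cl, cr, d))
    # one joint sign-flip test across all cluster pairs (shared subject
    # flips, max statistic over the union of supports) so the family-wise
    # error is controlled over the entire LI analysis, not per cluster
    supports: dict[tuple[int, int], np.ndarray] = {}
    li_by_pair: dict[tuple[int, int], list[np.ndarray]] = {}
    for cl, cr, _d in pairing:
        support = left_pref.per_cluster[cl].mask & flip(right_pref.per_cluster[cr].mask)
        supports[(cl, cr)] = support
        maps = []
        for zl_s, zr_s in zip(left_zmaps, right_zmaps):
            zl = np.where(support, zl_s[cl], np.nan)
            zr = np.where(support, flip(zr_s[cr]), np.nan)
            maps.append(lateralization(zl, zr, eps=eps).li[support])
        li_by_pair[(cl, cr)] = maps
    n_sub = len(left_zmaps)
    joint = [
        np.concatenate([li_by_pair[p][s] for p in supports]) for s in range(n_sub)
    ]
    res = permutation_onesample(joint, n_perm=n_perm, alpha=alpha, seed=seed)
    results: dict[tuple[int, int], PermutationResult] = {}
    offset = 0
    shape = next(iter(supports.values())).shape
    for p, support in supports.items():
        n_vox = int(support.sum())
        sl = slice(offset, offset + n_vox)
        offset += n_vox
        t_map = np.full(shape, np.nan)
        fwe_p = np.full(shape, np.nan)
        mask = np.zeros(shape, dtype=bool)
        t_map[support] = res.t_map[sl]
        fwe_p[support] = res.fwe_p[sl]
        mask[support] = res.mask[sl]
        results[p] = PermutationResult(t_map, fwe_p, mask, alpha, n_perm)
    return LateralizationResult(pairing, results)


def make_term_set(
    scene: SyntheticScene,
    planted_cluster: int,
    n_distractors: int = 19,
    seed: int = 0,
    blob_sigma_vox: float = 2.0,
) -> "object":
    """Synthetic decoding term maps: one planted match plus random decoys.

    The planted term is the (smoothed) indicator of the cluster's target
    territories; each distractor is a smoothed Gaussian blob at a random
    location.  Term names sort the planted map in the middle of the pack
    so ranking cannot succeed by name order.
    """
    from scipy import ndimage as ndi

    from .decode import TermMapSet

    rng = np.random.default_rng(seed)
    shape = scene.roi_left.shape
    maps: dict[str, Image3D] = {}
    planted = ndi.gaussian_filter(
        scene.target_regions[planted_cluster].data.astype(float), 1.0
    )
    maps[f"term_{planted_cluster:03d}_planted"] = scene.roi_left.like(planted)
    for i in range(n_distractors):
        blob = np.zeros(shape)
        c = rng.uniform(2, np.asarray(shape) - 3)
        blob[tuple(np.round(c).astype(int))] = 1.0
        blob = ndi.gaussian_filter(blob, blob_sigma_vox)
        blob /= blob.max()
        maps[f"term_{rng.integers(100, 1000):03d}_d{i:02d}"] = scene.roi_left.like(blob)
    return TermMapSet(maps)


# ---------------------------------------------------------------------------
# file-based driver


@dataclass
class PipelineConfig:
    """Configuration of a file-based pipeline run."""

    out_dir: Path
    bold_paths: list[Path] = field(default_factory=list)
    tracks_path: Path | None = None
    roi_left_path: Path | None = None
    roi_right_path: Path | None = None
    wm_prob_paths: list[Path] = field(default_factory=list)
    atlas_path: Path | None = None
    scene: SceneConfig | None = None  # simulate inputs instead of reading them
    window_length_tp: int = 40
    window_stride_tp: int = 1
    k_range: tuple[int, int] = (2, 9)
    k_select: int = 4
    n_init: int = 100
    n_resamples: int = 100
    n_perm: int = 5000
    alpha: float = 0.001
    dilation_mm: float = 4.0
    downsample_factor: int = 2
    fwhm_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.scene is None and not self.bold_paths:
            raise ValueError("either a scene config or BOLD inputs must be given")
        if not (2 <= self.window_length_tp):
            raise ValueError("window length must be >= 2 timepoints")
        if self.k_range[0] < 2 or self.k_range[1] < self.k_range[0]:
            raise ValueError("invalid k range")


def _checksum(*arrays: np.ndarray) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full pipeline and write outputs + manifest under out_dir."""
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "seed": cfg.seed}
    rng = np.random.default_rng(cfg.seed)

    # --- inputs ---------------------------------------------------------
    if cfg.scene is not None:
        scene = build_scene(cfg.scene)
        manifest["scene_config"] = scene_config_dict(cfg.scene)
        bolds = scene.bold_per_subject
        roi_l, roi_r = scene.roi_left, scene.roi_right
        wm_probs = [scene.wm_mask]
        atlas = scene.atlas_labels
        traversal = scene.traversal
        tio.write_tck(scene.streamlines, out / "tracks.tck")
        tio.write_image(roi_l, out / "roi_left.nii.gz")
        tio.write_image(roi_r, out / "roi_right.nii.gz")
        tio.write_image(atlas, out / "atlas.nii.gz")
    else:
        for p in [cfg.tracks_path, cfg.roi_left_path, cfg.roi_right_path]:
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"required input missing: {p}")
        for p in cfg.bold_paths + cfg.wm_prob_paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"required input missing: {p}")
        bolds = [tio.read_image(p) for p in cfg.bold_paths]
        roi_l = tio.read_image(cfg.roi_left_path)
        roi_r = tio.read_image(cfg.roi_right_path)
        wm_probs = [tio.read_image(p) for p in cfg.wm_prob_paths]
        atlas = tio.read_image(cfg.atlas_path) if cfg.atlas_path else None
        tracks = tio.read_tck(cfg.tracks_path)
        traversal = build_traversal_index(tracks, roi_l)

    window = WindowSpec(cfg.window_length_tp, cfg.window_stride_tp)
    wm_mask = make_wm_mask(wm_probs, [roi_l, roi_r], cfg.dilation_mm)
    shape = roi_l.shape

    fps_by_hemi: dict[str, list] = {"L": [], "R": []}
    for b in bolds:
        tw = subject_twdfc(b, traversal, window, cfg.fwhm_mm)
        fps_by_hemi["L"].append(subject_fingerprint(tw, roi_l, wm_mask, cfg.downsample_factor))
        fps_by_hemi["R"].append(subject_fingerprint(tw, roi_r, wm_mask, cfg.downsample_factor))

    report: dict = {"hemispheres": {}}
    for hemi, roi in (("L", roi_l), ("R", roi_r)):
        stage = f"parcellate_{hemi}"
        try:
            fps = fps_by_hemi[hemi]
            hemi_report: dict = {"k": {}}
            partitions_by_k: dict[int, list[Partition]] = {}
            group_by_k: dict[int, Partition] = {}
            for k in range(cfg.k_range[0], cfg.k_range[1] + 1):
                subs = [
                    kmeans_partition(fp, k, cfg.n_init, int(rng.integers(0, 2**31 - 1)))
                    for fp in fps
                ]
                grp = consensus(subs, k, cfg.n_init, int(rng.integers(0, 2**31 - 1)))
                partitions_by_k[k] = subs
                group_by_k[k] = grp
                sil = [float(silhouette(fp.matrix, p)) for fp, p in zip(fps, subs)]
                hemi_report["k"][k] = {
                    "silhouette_individual_mean": float(np.mean(sil)),
                    "silhouette_individual_sd": float(np.std(sil)),
                }
                if len(fps) >= 4:
                    nvis = splithalf_nvi(
                        subs, k, cfg.n_resamples, int(rng.integers(0, 2**31 - 1)), cfg.n_init
                    )
                    hemi_report["k"][k]["nvi_median"] = float(np.median(nvis))
                lab = group_by_k[k].to_label_volume(shape)
                tio.write_image(Image3D(lab, roi.affine), out / f"labels_{hemi}_k{k}.nii.gz")
            manifest["stages"][stage] = {
                "checksum": _checksum(
                    *[group_by_k[k].labels for k in sorted(group_by_k)]
                )
            }
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc

        stage = f"characterize_{hemi}"
        try:
            ksel = cfg.k_select
            group = group_by_k[ksel]
            if atlas is not None:
                table = overlap_table(group, atlas, shape)
                table.to_csv(out / f"overlap_{hemi}_k{ksel}.tsv", sep="\t")
                hemi_report["overlap_table"] = table.to_dict()
            hemi_report["consensus_labels_k_select"] = group.labels.tolist()
            manifest["stages"][stage] = {"checksum": _checksum(group.labels)}
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc
        report["hemispheres"][hemi] = hemi_report

    tio.write_json(report, out / "report.json")
    manifest["stages"]["report"] = {"checksum": _checksum(np.frombuffer(
        (out / "report.json").read_bytes(), dtype=np.uint8
    ))}
    tio.write_json(manifest, out / "manifest.json")
    return report
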