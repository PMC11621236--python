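"""Cluster-number selection and reproducibility metrics.

Four complementary criteria are surfaced (the choice of k is deliberately
left to the analyst):

* silhouette — segregation of the clustering solution in its feature space,
  in [-1, 1];
* normalized variation of information (nVI) over split-half resamples —
  stability of the group consensus under subsampling, in [0, 1] (VI with
  natural logs, normalized by ln N so "one cluster vs all singletons" = 1);
* one-way ANOVA with Tukey HSD post hoc — whether criteria differ across k;
* Dice-based cluster matching — reproducibility of corresponding parcels
  across independent datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import silhouette_score
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .parcellate import Partition, consensus

logger = logging.getLogger(__name__)

__all__ = [
    "silhouette",
    "nvi",
    "splithalf_nvi",
    "compare_k",
    "AnovaTukeyResult",
    "dice",
    "match_and_average_dice",
]


def silhouette(features: np.ndarray, partition: Partition | np.ndarray) -> float:
    """Mean silhouette score of a partition in Euclidean feature space.

    For each point, s = (b - a)/max(a, b) with a the mean distance to its
    own cluster and b the smallest mean distance to another cluster;
    singleton clusters and zero-distance degeneracies contribute 0.
    """
    labels = partition.labels if isinstance(partition, Partition) else np.asarray(partition)
    x = np.asarray(features, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    return float(silhouette_score(x, labels, metric="euclidean"))


def _entropy_nats(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def nvi(p1: Partition | np.ndarray, p2: Partition | np.ndarray) -> float:
    """Normalized variation of information between two partitions.

    VI = H(p1) + H(p2) - 2 I(p1, p2), natural logarithms, normalized by
    ln N (N = number of points): 0 iff the partitions coincide up to
    relabelling; 1 for one-cluster vs all-singletons.
    """
    l1 = p1.labels if isinstance(p1, Partition) else np.asarray(p1)
    l2 = p2.labels if isinstance(p2, Partition) else np.asarray(p2)
    if l1.shape != l2.shape:
        raise ValueError("partitions cover different numbers of points")
    n = l1.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    u1, inv1 = np.unique(l1, return_inverse=True)
    u2, inv2 = np.unique(l2, return_inverse=True)
    cont = np.zeros((u1.size, u2.size))
    np.add.at(cont, (inv1, inv2), 1.0)
    # identical up to relabelling -> exactly 0 (one nonzero per row and column)
    if ((cont > 0).sum(axis=0) == 1).all() and ((cont > 0).sum(axis=1) == 1).all():
        return 0.0
    pxy = cont / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    mi = float((pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])).sum())
    vi = _entropy_nats(l1) + _entropy_nats(l2) - 2.0 * mi
    return max(0.0, vi / np.log(n))


def splithalf_nvi(
    subject_partitions: list[Partition],
    k: int,
    n_resamples: int = 100,
    seed: int = 0,
    n_init: int = 100,
) -> np.ndarray:
    """Stability of the group consensus under split-half resampling.

    Per resample the subjects are split into two disjoint random halves
    (with an odd count, the first half receives the extra subject), a
    consensus partition is computed per half at this k, and the nVI between
    the two half-consensus partitions is recorded.
    """
    n_sub = len(subject_partitions)
    if n_sub < 4:
        raise ValueError("split-half resampling needs at least 4 subjects")
    rng = np.random.default_rng(seed)
    out = np.empty(n_resamples)
    half = (n_sub + 1) // 2
    for i in range(n_resamples):
        order = rng.permutation(n_sub)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        pa = consensus([subject_partitions[j] for j in order[:half]], k, n_init, sub_seed)
        pb = consensus(
            [subject_partitions[j] for j in order[half:]], k, n_init, sub_seed + 1
        )
        out[i] = nvi(pa, pb)
    return out


@dataclass
class AnovaTukeyResult:
    """One-way ANOVA across k plus Tukey HSD pairwise comparisons."""

    f_statistic: float
    p_value: float
    tukey: pd.DataFrame  # columns: group1, group2, meandiff, p_adj, reject

    def significant_pairs(self, alpha: float = 0.05) -> list[tuple]:
        sel = self.tukey[self.tukey["p_adj"] < alpha]
        return list(zip(sel["group1"], sel["group2"]))


def compare_k(scores_by_k: dict[int, np.ndarray]) -> AnovaTukeyResult:
    """Do validity scores differ across candidate cluster numbers k?"""
    keys = sorted(scores_by_k)
    if len(keys) < 2:
        raise ValueError("need at least 2 groups")
    groups = [np.asarray(scores_by_k[k], dtype=float) for k in keys]
    for g in groups:
        if g.size < 2:
            raise ValueError("each group needs at least 2 samples")
    if all(np.allclose(g.var(), 0) for g in groups):
        raise ValueError("zero within-group variance everywhere; F undefined")
    f, p = stats.f_oneway(*groups)
    values = np.concatenate(groups)
    labels = np.concatenate([[k] * len(g) for k, g in zip(keys, groups)])
    res = pairwise_tukeyhsd(values, labels)
    frame = pd.DataFrame(
        res.summary().data[1:], columns=[c.replace("-", "_") for c in res.summary().data[0]]
    )
    frame = frame.rename(columns={"p_adj": "p_adj"})
    return AnovaTukeyResult(float(f), float(p), frame)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|a n b| / (|a| + |b|); two empty sets count as identical."""
    a = np.asarray(a) > 0
    b = np.asarray(b) > 0
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def match_and_average_dice(
    pa: Partition, pb: Partition, shape: tuple[int, int, int] | None = None
) -> tuple[list[tuple[int, int, float]], float]:
    """Greedy max-Dice matching of clusters across two partitions.

    Pairs are matched in descending order of pairwise Dice, each cluster
    used at most once (ties broken by the lower index pair); returns the
    matched (label_a, label_b, dice) triples and the mean Dice over matched
    pairs.  Unmatched clusters (unequal k) are logged.
    """
    if shape is None:
        all_vox = np.vstack([pa.voxel_list, pb.voxel_list])
        shape = tuple(int(m) + 1 for m in all_vox.max(axis=0))
    masks_a = {la: pa.cluster_mask(la, shape) for la in range(1, pa.k + 1)}
    masks_b = {lb: pb.cluster_mask(lb, shape) for lb in range(1, pb.k + 1)}
    pairs = []
    for la, ma in masks_a.items():
        for lb, mb in masks_b.items():
            pairs.append((dice(ma, mb), la, lb))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched: list[tuple[int, int, float]] = []
    for d, la, lb in pairs:
        if la in used_a or lb in used_b:
            continue
        used_a.add(la)
        used_b.add(lb)
        matched.append((la, lb, d))
    unmatched = (set(masks_a) - used_a) | set(
        -lb for lb in set(masks_b) - used_b
    )
    if unmatched:
        logger.info("unmatched clusters after greedy Dice matching: %s", sorted(unmatched))
    avg = float(np.mean([d for _, _, d in matched])) if matched else 0.0
    return matched, avg
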