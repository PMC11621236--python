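"""Decoding mechanics: track-weighted term maps ranked by spatial correlation.

A set of scalar "term" maps (stand-ins for meta-analytic predictive
activation maps) is first masked to grey matter, then redistributed onto
white matter by track-weighting with a template streamline set, and finally
ranked by Pearson correlation against a cluster's connectivity map.  The
term database itself is out of scope: the module operates on any supplied
map set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .images import Image3D
from .tractmap import StreamlineSet, TraversalIndex, build_traversal_index, track_weight_scalar_map

logger = logging.getLogger(__name__)

__all__ = ["TermMapSet", "gm_mask_map", "track_weight_terms", "rank_terms", "merge_tractograms"]


@dataclass
class TermMapSet:
    """Named scalar maps on a common analysis grid."""

    maps: dict[str, Image3D]

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.maps.values()}
        if len(shapes) > 1:
            raise ValueError(f"term maps on inconsistent grids: {shapes}")

    def __len__(self) -> int:
        return len(self.maps)


def gm_mask_map(map_: Image3D, gm_mask: Image3D) -> Image3D:
    """Zero a map outside a grey-matter mask."""
    m = np.asarray(gm_mask.data) > 0
    if not m.any():
        raise ValueError("grey-matter mask is empty")
    out = np.where(m, np.asarray(map_.data, dtype=float), 0.0)
    if not np.any(out):
        logger.warning("map support does not intersect the GM mask; output is all zero")
    return map_.like(out)


def track_weight_terms(
    terms: TermMapSet,
    template: StreamlineSet,
    index: TraversalIndex | None = None,
) -> TermMapSet:
    """Track-weight every term map with the template streamline set."""
    if len(template) == 0:
        raise ValueError("template streamline set is empty")
    if index is None:
        first = next(iter(terms.maps.values()))
        index = build_traversal_index(template, first)
    out = {
        name: track_weight_scalar_map(template, m, index=index)
        for name, m in terms.maps.items()
    }
    return TermMapSet(out)


def rank_terms(
    conn_map: Image3D,
    tw_terms: TermMapSet,
    top_n: int = 20,
    mask: np.ndarray | None = None,
) -> list[tuple[str, float]]:
    """Rank term maps by Pearson correlation with a connectivity map.

    Correlation is computed over in-mask finite voxels (default: voxels
    where the connectivity map is finite); zero-variance terms are excluded
    (logged).  Descending by r, ties broken by name; at most ``top_n``
    entries returned.
    """
    if len(tw_terms) == 0:
        raise ValueError("no term maps supplied")
    conn = np.asarray(conn_map.data, dtype=float)
    sel = np.isfinite(conn)
    if mask is not None:
        sel &= np.asarray(mask) > 0
    x = conn[sel]
    x = x - x.mean()
    sx = np.sqrt((x**2).sum())
    if sx == 0:
        raise ValueError("connectivity map has zero variance over the mask")
    scored: list[tuple[str, float]] = []
    for name, m in tw_terms.maps.items():
        y = np.asarray(m.data, dtype=float)[sel]
        y = np.where(np.isfinite(y), y, 0.0)
        y = y - y.mean()
        sy = np.sqrt((y**2).sum())
        if sy == 0:
            logger.info("term %r has zero variance over the mask; excluded", name)
            continue
        scored.append((name, float((x @ y) / (sx * sy))))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored[: min(top_n, len(scored))]


def merge_tractograms(
    sets: list[StreamlineSet], per_subject_n: int | None = None, seed: int = 0
) -> StreamlineSet:
    """Merge per-subject streamline sets into a template tractogram,
    optionally downsampling each to ``per_subject_n`` streamlines first."""
    rng = np.random.default_rng(seed)
    merged: list[np.ndarray] = []
    for ss in sets:
        lines = list(ss.streamlines)
        if per_subject_n is not None and len(lines) > per_subject_n:
            idx = rng.choice(len(lines), size=per_subject_n, replace=False)
            lines = [lines[i] for i in sorted(idx)]
        merged.extend(lines)
    return StreamlineSet(merged)
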