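"""Merging of over-segmented labels.

Over-segmentation is the intended intermediate of the workflow (merging is
easier than splitting), so post-processing only ever unifies labels: from
an explicit pair list (proofreading), or automatically along a growth axis
for columnar structures, where pieces of one broken column stack along the
axis with near-identical cross-sections while distinct neighboring columns
barely overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import LabelVolume
from .quantify import build_rag

_AXES = {"z": 0, "y": 1, "x": 2}


@dataclass(frozen=True)
class MergeDirective:
    """An order-independent list of label pairs to unify (union semantics)."""

    pairs: tuple = ()

    def __init__(self, pairs) -> None:
        object.__setattr__(self, "pairs", tuple((int(a), int(b)) for a, b in pairs))


@dataclass(frozen=True)
class DirectedMergeParams:
    """Gates of the automatic growth-direction merge.

    A pair of touching labels is merged when (a) the angle between their
    centroid difference and ``growth_axis`` is at most ``angle_tolerance``
    degrees, (b) their axis-perpendicular footprints overlap by at least
    ``min_overlap_fraction`` of the smaller footprint, and (c) the gap
    between their axis extents is at most ``max_gap`` voxels.  Applied to a
    fixed point in deterministic (ascending label pair) order.
    """

    growth_axis: str = "z"
    angle_tolerance: float = 30.0
    min_overlap_fraction: float = 0.5
    max_gap: int = 3

    def __post_init__(self) -> None:
        if self.growth_axis not in _AXES:
            raise ValueError("growth_axis must be one of 'z', 'y', 'x'")
        if not 0.0 < self.angle_tolerance < 90.0:
            raise ValueError("angle_tolerance must be in (0, 90) degrees")
        if not 0.0 < self.min_overlap_fraction <= 1.0:
            raise ValueError("min_overlap_fraction must be in (0, 1]")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")


class _UnionFind:
    def __init__(self, items) -> None:
        self.parent = {i: i for i in items}

    def find(self, i):
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # collapse to the smaller label
            lo, hi = min(ra, rb), max(ra, rb)
            self.parent[hi] = lo


def _collapse(labels: LabelVolume, uf: _UnionFind) -> LabelVolume:
    max_label = int(labels.data.max())
    lut = np.arange(max_label + 1, dtype=labels.data.dtype)
    for lab in uf.parent:
        lut[lab] = uf.find(lab)
    return LabelVolume(lut[labels.data], labels.spacing)


def apply_merges(labels: LabelVolume, directive: MergeDirective) -> LabelVolume:
    """Unify the listed label pairs; each connected pair set collapses to
    its smallest member label.  Unknown labels are an error."""
    present = set(int(l) for l in labels.labels())
    named = {l for pair in directive.pairs for l in pair}
    unknown = sorted(named - present)
    if unknown:
        raise ValueError(f"merge directive names absent labels: {unknown}")
    if not directive.pairs:
        return LabelVolume(labels.data.copy(), labels.spacing)
    uf = _UnionFind(present)
    for a, b in directive.pairs:
        uf.union(a, b)
    return _collapse(labels, uf)


def _label_geometry(labels: LabelVolume, axis: int):
    """Per-label centroid, axis extent, and axis-perpendicular footprint."""
    data = labels.data
    other = tuple(a for a in range(3) if a != axis)
    geo = {}
    for lab in labels.labels():
        lab = int(lab)
        where = np.nonzero(data == lab)
        coords = np.column_stack(where).astype(np.float64)
        centroid = coords.mean(axis=0)
        ax_min, ax_max = int(where[axis].min()), int(where[axis].max())
        fp = np.zeros((data.shape[other[0]], data.shape[other[1]]), dtype=bool)
        fp[where[other[0]], where[other[1]]] = True
        geo[lab] = (centroid, ax_min, ax_max, fp)
    return geo


def directed_merge(labels: LabelVolume, params: DirectedMergeParams = DirectedMergeParams()) -> LabelVolume:
    """Merge touching labels preferentially along the growth axis.

    Iterates build-graph / gate / merge until no pair qualifies; idempotent
    at the fixed point.  The foreground voxel set never changes.
    """
    axis = _AXES[params.growth_axis]
    e = np.zeros(3)
    e[axis] = 1.0
    cos_tol = np.cos(np.deg2rad(params.angle_tolerance))

    current = LabelVolume(labels.data.copy(), labels.spacing)
    while True:
        rag = build_rag(current, min_contact=1)
        geo = _label_geometry(current, axis)
        uf = _UnionFind(list(geo))
        merged_any = False
        for a, b in sorted(tuple(sorted(edge)) for edge in rag.edges):
            ca, amin_a, amax_a, fp_a = geo[a]
            cb, amin_b, amax_b, fp_b = geo[b]
            vec = cb - ca
            norm = np.linalg.norm(vec)
            if norm == 0:
                continue
            if abs(float(vec @ e)) / norm < cos_tol:
                continue
            overlap = np.logical_and(fp_a, fp_b).sum() / min(fp_a.sum(), fp_b.sum())
            if overlap < params.min_overlap_fraction:
                continue
            gap = max(0, max(amin_b - amax_a, amin_a - amax_b) - 1)
            if gap > params.max_gap:
                continue
            uf.union(a, b)
            merged_any = True
        if not merged_any:
            return current
        current = _collapse(current, uf)
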