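"""Contour-tree region growing with topological-persistence merging.

Foreground voxels are swept in strictly decreasing distance-map order (ties
broken by ascending linear index, making the sweep a pure function of the
input).  A voxel with no labeled stencil neighbor founds a region at its
value (a local-maximum birth); a voxel adjacent to exactly one region joins
it; a voxel adjacent to several regions is a saddle, where every adjacent
region whose persistence (region peak minus saddle value) falls below the
persistence threshold is merged into the adjacent region with the globally
highest peak, and the voxel joins that surviving region.

Regions whose peak equals the saddle value are always unified: they are
zero-persistence births on the same level set (one plateau), not distinct
maxima, so a persistence threshold of 0 still yields exactly one label per
plateau-aware local maximum while never merging genuinely distinct maxima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from ._stencil import stencil_offsets
from .grids import DistanceMap, LabelVolume


@dataclass(frozen=True)
class SegmentationParams:
    """Knobs of the contour-tree sweep.

    persistence_threshold
        Minimum peak-minus-saddle depth a region needs to survive a saddle,
        on the (normalized, if ``normalize_first``) distance-value scale;
        0 disables merging of distinct maxima entirely.
    connectivity
        Region-growing adjacency (defaults to the walk stencil's 6).
    normalize_first
        Min-max normalize the map before sweeping, so the threshold lives
        on a [0, 1] scale.
    """

    persistence_threshold: float = 0.15
    connectivity: int = 6
    normalize_first: bool = True

    def __post_init__(self) -> None:
        if self.persistence_threshold < 0:
            raise ValueError("persistence_threshold must be >= 0")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


@njit(cache=True)
def _find(parent, i):
    root = i
    while parent[root] != root:
        root = parent[root]
    while parent[i] != root:
        nxt = parent[i]
        parent[i] = root
        i = nxt
    return root


@njit(cache=True)
def _sweep(order, nbr_table, nbr_count, values, threshold):
    """Union-find sweep over foreground voxels in decreasing-value order.

    order        : compact fg ids sorted by decreasing value / ascending index
    nbr_table    : (n, stencil) compact fg neighbor ids, -1 padding
    nbr_count    : valid entries per row
    values       : per-compact-id map values
    Returns per-voxel root region ids (compact-id space).
    """
    n = order.size
    parent = np.full(n, -1, dtype=np.int64)
    peak = np.zeros(n, dtype=np.float64)
    region_of = np.full(n, -1, dtype=np.int64)
    roots_buf = np.empty(32, dtype=np.int64)

    for oi in range(n):
        v = order[oi]
        val = values[v]
        k = 0
        for j in range(nbr_count[v]):
            u = nbr_table[v, j]
            if region_of[u] < 0:
                continue
            r = _find(parent, region_of[u])
            dup = False
            for t in range(k):
                if roots_buf[t] == r:
                    dup = True
                    break
            if not dup:
                roots_buf[k] = r
                k += 1
        if k == 0:
            parent[v] = v
            peak[v] = val
            region_of[v] = v
        elif k == 1:
            region_of[v] = roots_buf[0]
        else:
            target = roots_buf[0]
            for t in range(1, k):
                r = roots_buf[t]
                if peak[r] > peak[target] or (peak[r] == peak[target] and r < target):
                    target = r
            for t in range(k):
                r = roots_buf[t]
                if r == target:
                    continue
                if (peak[r] - val) < threshold or peak[r] == val:
                    parent[r] = target
            region_of[v] = target

    out = np.empty(n, dtype=np.int64)
    for i in range(n):
        out[i] = _find(parent, region_of[i])
    return out


def contour_tree_segment(dmap: DistanceMap, params: SegmentationParams = SegmentationParams()) -> LabelVolume:
    """Segment a distance map into labels by the persistence-merged sweep.

    Output labels exactly cover the map's foreground (background stays 0)
    and are numbered 1..K in order of region founding, so label 1 contains
    the global maximum.  Deterministic for identical inputs.
    """
    mask = dmap.mask
    if mask.foreground_count == 0:
        raise ValueError("distance map has empty foreground")
    if params.normalize_first:
        from .distance import minmax_normalize

        dmap = minmax_normalize(dmap)

    m = mask.data
    shape = m.shape
    fg_flat = np.flatnonzero(m.ravel())
    n = fg_flat.size
    compact = -np.ones(m.size, dtype=np.int64)
    compact[fg_flat] = np.arange(n)
    values = dmap.data.ravel()[fg_flat]

    offsets = stencil_offsets(params.connectivity)
    coords = np.column_stack(np.unravel_index(fg_flat, shape))
    table = np.full((n, len(offsets)), -1, dtype=np.int64)
    count = np.zeros(n, dtype=np.int64)
    for off in offsets:
        nb = coords + off
        inside = ((nb >= 0) & (nb < np.array(shape))).all(axis=1)
        nb_flat = np.ravel_multi_index((nb[inside, 0], nb[inside, 1], nb[inside, 2]), shape)
        nb_c = compact[nb_flat]
        src = np.flatnonzero(inside)[nb_c >= 0]
        tgt = nb_c[nb_c >= 0]
        table[src, count[src]] = tgt
        count[src] += 1

    # stable sort on -values keeps ascending linear index among ties
    order = np.argsort(-values, kind="stable").astype(np.int64)
    roots = _sweep(order, table, count, values.astype(np.float64),
                   float(params.persistence_threshold))

    # relabel roots 1..K by founding order (sweep position of the root voxel)
    sweep_pos = np.empty(n, dtype=np.int64)
    sweep_pos[order] = np.arange(n)
    uniq_roots = np.unique(roots)
    by_founding = uniq_roots[np.argsort(sweep_pos[uniq_roots], kind="stable")]
    lut = np.zeros(n, dtype=np.int64)
    lut[by_founding] = np.arange(1, uniq_roots.size + 1)

    out = np.zeros(m.size, dtype=np.int32)
    out[fg_flat] = lut[roots]
    return LabelVolume(out.reshape(shape), mask.spacing)


def count_local_maxima(dmap: DistanceMap, connectivity: int = 6) -> int:
    """Plateau-aware local maxima of the map over its foreground.

    A maximum is a connected set of equal-valued foreground voxels none of
    whose stencil neighbors (foreground only; background counts as the
    absolute minimum) has a strictly greater value; each plateau counts
    once.
    """
    mask = dmap.mask
    if mask.foreground_count == 0:
        raise ValueError("distance map has empty foreground")
    m = mask.data
    shape = m.shape
    fg_flat = np.flatnonzero(m.ravel())
    n = fg_flat.size
    compact = -np.ones(m.size, dtype=np.int64)
    compact[fg_flat] = np.arange(n)
    values = dmap.data.ravel()[fg_flat]

    offsets = stencil_offsets(connectivity)
    coords = np.column_stack(np.unravel_index(fg_flat, shape))
    has_greater = np.zeros(n, dtype=bool)
    eq_rows, eq_cols = [], []
    for off in offsets:
        nb = coords + off
        inside = ((nb >= 0) & (nb < np.array(shape))).all(axis=1)
        nb_flat = np.ravel_multi_index((nb[inside, 0], nb[inside, 1], nb[inside, 2]), shape)
        nb_c = compact[nb_flat]
        ok = nb_c >= 0
        src = np.flatnonzero(inside)[ok]
        tgt = nb_c[ok]
        gv = values[tgt] > values[src]
        has_greater[src[gv]] = True
        eq = values[tgt] == values[src]
        eq_rows.append(src[eq])
        eq_cols.append(tgt[eq])

    rows = np.concatenate(eq_rows)
    cols = np.concatenate(eq_cols)
    adj = coo_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
    n_plateau, plateau = connected_components(adj, directed=False)
    plateau_has_greater = np.zeros(n_plateau, dtype=bool)
    np.logical_or.at(plateau_has_greater, plateau, has_greater)
    return int((~plateau_has_greater).sum())
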