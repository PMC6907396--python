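"""Per-label morphometrics and segmentation evaluation.

Covers the measurements used in the three tiled-tissue case studies:
region adjacency (neighbor/side counts as a geometry proxy), per-tile
volume, mean intensity (a mineral-density proxy) and principal extents,
per-prism radius profiles R(z) = sqrt(A/pi) along a growth axis with
Hillert-style growth/shrink classification, and overlap-based evaluation
of a predicted labeling against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .grids import IntensityVolume, LabelVolume

_AXES = {"z": 0, "y": 1, "x": 2}


@dataclass
class TileStats:
    label: int
    voxel_count: int
    volume: float
    neighbor_count: int
    mean_intensity: float
    centroid: tuple[float, float, float]
    principal_extents: tuple[float, float, float]


@dataclass
class PrismProfile:
    label: int
    z_indices: np.ndarray
    area: np.ndarray
    radius: np.ndarray
    slope: float  # dR/dz in physical units; NaN when present in < 2 slices
    growth_class: str  # "growing" iff slope > 0
    relative_curvature: float  # mean_z (1/Rbar(z) - 1/R_i(z))


@dataclass
class SegmentationReport:
    n_truth: int
    n_predicted: int
    n_matched_one_to_one: int
    n_split: int
    n_merged: int

    def as_dict(self) -> dict:
        return {
            "n_truth": self.n_truth,
            "n_predicted": self.n_predicted,
            "n_matched_one_to_one": self.n_matched_one_to_one,
            "n_split": self.n_split,
            "n_merged": self.n_merged,
        }


def _face_contacts(data: np.ndarray):
    """All face-adjacent (6-connectivity) voxel pairs with two distinct
    positive labels, as (label_a, label_b) arrays."""
    pairs = []
    for axis in range(3):
        a = np.take(data, range(data.shape[axis] - 1), axis=axis).ravel()
        b = np.take(data, range(1, data.shape[axis]), axis=axis).ravel()
        sel = (a != b) & (a > 0) & (b > 0)
        pairs.append(np.column_stack([a[sel], b[sel]]))
    allp = np.concatenate(pairs) if pairs else np.empty((0, 2), dtype=data.dtype)
    return np.sort(allp, axis=1)


def build_rag(labels: LabelVolume, min_contact: int = 1) -> nx.Graph:
    """Region adjacency graph: nodes are labels, edges carry the number of
    face-adjacent voxel pairs spanning the two labels (``contact_count``);
    edges below ``min_contact`` are dropped.  Background is never a node."""
    g = nx.Graph()
    g.add_nodes_from(int(l) for l in labels.labels())
    pairs = _face_contacts(labels.data)
    if pairs.size:
        uniq, counts = np.unique(pairs, axis=0, return_counts=True)
        for (a, b), c in zip(uniq, counts):
            if c >= min_contact:
                g.add_edge(int(a), int(b), contact_count=int(c))
    return g


def tile_stats(
    labels: LabelVolume, intensity: IntensityVolume, rag: nx.Graph
) -> list[TileStats]:
    """One morphometric record per nonzero label.

    Volume is voxel count times the spacing product; principal extents are
    4*sqrt(eigenvalue) of the physical voxel-coordinate covariance per
    principal axis (a full-width proxy), sorted descending.
    """
    if labels.shape != intensity.shape:
        raise ValueError(f"shape mismatch: labels {labels.shape} vs intensity {intensity.shape}")
    data = labels.data
    ids = labels.labels()
    max_label = int(data.max())
    flat = data.ravel()
    counts = np.bincount(flat, minlength=max_label + 1)
    isum = np.bincount(flat, weights=intensity.data.ravel(), minlength=max_label + 1)

    sp = np.array(labels.spacing)
    voxel_volume = float(np.prod(sp))
    coords = [np.arange(data.shape[a], dtype=np.float64) * sp[a] for a in range(3)]
    grids = np.meshgrid(*coords, indexing="ij")
    csum = np.column_stack(
        [np.bincount(flat, weights=g.ravel(), minlength=max_label + 1) for g in grids]
    )
    # second moments for the covariance eigen-extents
    msum = {}
    for i in range(3):
        for j in range(i, 3):
            msum[(i, j)] = np.bincount(
                flat, weights=(grids[i] * grids[j]).ravel(), minlength=max_label + 1
            )

    out = []
    for lab in ids:
        lab = int(lab)
        n = int(counts[lab])
        centroid = csum[lab] / n
        cov = np.empty((3, 3))
        for i in range(3):
            for j in range(i, 3):
                cov[i, j] = cov[j, i] = msum[(i, j)][lab] / n - centroid[i] * centroid[j]
        eig = np.clip(np.linalg.eigvalsh(cov), 0.0, None)
        extents = tuple(sorted((4.0 * np.sqrt(eig)).tolist(), reverse=True))
        out.append(
            TileStats(
                label=lab,
                voxel_count=n,
                volume=n * voxel_volume,
                neighbor_count=rag.degree(lab) if lab in rag else 0,
                mean_intensity=float(isum[lab] / n),
                centroid=tuple(centroid.tolist()),
                principal_extents=extents,  # type: ignore[arg-type]
            )
        )
    return out


def neighbor_histogram(stats: list[TileStats]):
    """Counts and fractions per neighbor count, plus the arithmetic mean."""
    if not stats:
        raise ValueError("stats must be non-empty")
    ns = np.array([s.neighbor_count for s in stats])
    hist = {}
    for k in np.unique(ns):
        c = int((ns == k).sum())
        hist[int(k)] = (c, c / ns.size)
    return hist, float(ns.mean())


def prism_profiles(labels: LabelVolume, growth_axis: str = "z") -> list[PrismProfile]:
    """Radius profile, growth slope, and relative curvature per column.

    Per label and slice along ``growth_axis``: A(z) = voxel count times the
    in-plane voxel area and R(z) = sqrt(A/pi).  The slope is the ordinary
    least-squares dR/dz over the label's extent (physical units); the class
    is "growing" iff slope > 0.  Relative curvature averages
    ``1/Rbar(z) - 1/R_i(z)`` over the label's slices, where Rbar(z) is the
    mean radius of all labels present in slice z — Hillert's critical
    radius proxy, against which larger-than-average columns grow and
    smaller ones shrink.  Labels present in fewer than 2 slices get a NaN
    slope and should be excluded from trend statistics.
    """
    axis = _AXES[growth_axis]
    data = np.moveaxis(labels.data, axis, 0)
    nz = data.shape[0]
    if nz < 2:
        raise ValueError("labels must span at least 2 slices along the growth axis")
    sp = np.array(labels.spacing)
    step = float(sp[axis])
    plane_area = float(np.prod(np.delete(sp, axis)))

    max_label = int(labels.data.max())
    counts = np.zeros((max_label + 1, nz), dtype=np.int64)
    for z in range(nz):
        counts[:, z] = np.bincount(data[z].ravel(), minlength=max_label + 1)
    counts = counts[1:]  # drop background row; label k -> row k-1

    radius = np.sqrt(counts * plane_area / np.pi)
    present = counts > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_r = np.where(present, 1.0 / radius, np.nan)
    rbar = np.full(nz, np.nan)
    any_present = present.any(axis=0)
    rbar[any_present] = np.nanmean(np.where(present, radius, np.nan), axis=0)[any_present]

    zs = np.arange(nz, dtype=np.float64) * step
    out = []
    for row, lab in enumerate(range(1, max_label + 1)):
        sel = present[row]
        if not sel.any():
            continue
        r = radius[row, sel]
        z = zs[sel]
        if sel.sum() >= 2:
            slope = float(np.polyfit(z, r, 1)[0])
        else:
            slope = float("nan")
        rel_curv = float(np.nanmean(1.0 / rbar[sel] - inv_r[row, sel]))
        out.append(
            PrismProfile(
                label=lab,
                z_indices=np.flatnonzero(sel),
                area=counts[row, sel] * plane_area,
                radius=r,
                slope=slope,
                growth_class="growing" if slope > 0 else "shrinking",
                relative_curvature=rel_curv,
            )
        )
    return out


def evaluate_segmentation(predicted: LabelVolume, truth: LabelVolume) -> SegmentationReport:
    """Overlap-based comparison of a predicted labeling with ground truth.

    Each predicted label maps to the truth label holding the majority of
    its voxels.  A truth label is matched one-to-one iff exactly one
    predicted label maps to it; ``n_split`` counts truth labels receiving
    two or more predicted labels; ``n_merged`` counts predicted labels
    whose majority covers under 60% of their voxels or that dominate
    (hold the plurality of) two or more truth labels.
    """
    if predicted.shape != truth.shape:
        raise ValueError(f"shape mismatch: {predicted.shape} vs {truth.shape}")
    pred = predicted.data.ravel()
    tru = truth.data.ravel()
    sel = pred > 0
    pred = pred[sel]
    tru = tru[sel]

    pairs = np.column_stack([pred, tru])
    uniq, counts = np.unique(pairs, axis=0, return_counts=True)

    pred_ids = predicted.labels()
    truth_ids = truth.labels()
    pred_total = {int(p): 0 for p in pred_ids}
    majority: dict[int, tuple[int, int]] = {}  # pred -> (truth, overlap)
    for (p, t), c in zip(uniq, counts):
        p, t, c = int(p), int(t), int(c)
        pred_total[p] = pred_total.get(p, 0) + c
        if p not in majority or c > majority[p][1] or (c == majority[p][1] and t < majority[p][0]):
            majority[p] = (t, c)

    # how many predicted labels map (by majority) to each truth label
    recv: dict[int, int] = {}
    for p, (t, _) in majority.items():
        if t > 0:
            recv[t] = recv.get(t, 0) + 1

    # plurality predicted label per truth label
    truth_best: dict[int, tuple[int, int]] = {}
    for (p, t), c in zip(uniq, counts):
        p, t, c = int(p), int(t), int(c)
        if t == 0:
            continue
        if t not in truth_best or c > truth_best[t][1] or (c == truth_best[t][1] and p < truth_best[t][0]):
            truth_best[t] = (p, c)
    dominate_count: dict[int, int] = {}
    for t, (p, _) in truth_best.items():
        dominate_count[p] = dominate_count.get(p, 0) + 1

    n_matched = sum(1 for t in truth_ids if recv.get(int(t), 0) == 1)
    n_split = sum(1 for t in truth_ids if recv.get(int(t), 0) >= 2)
    n_merged = 0
    for p in pred_ids:
        p = int(p)
        t, c = majority.get(p, (0, 0))
        frac = c / pred_total[p] if pred_total[p] else 0.0
        if frac < 0.6 or dominate_count.get(p, 0) >= 2:
            n_merged += 1
    return SegmentationReport(
        n_truth=int(truth_ids.size),
        n_predicted=int(pred_ids.size),
        n_matched_one_to_one=n_matched,
        n_split=n_split,
        n_merged=n_merged,
    )
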