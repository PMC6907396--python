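"""Synthetic tiled-structure phantoms with known ground truth.

Three generators emulate the geometries the segmentation workflow targets:

* :func:`voronoi_tiling_phantom` — a slab of similarly sized tiles in direct
  contact, joined through mid-thickness constrictions with no resolved
  boundary (tessellated-cartilage-like geometry);
* :func:`hexagonal_tiling_phantom` — the same slab construction on a regular
  hexagonal lattice, giving every interior tile exactly six neighbors;
* :func:`columnar_prism_phantom` — columnar prisms along a growth axis whose
  cross-sections coarsen by a Hillert-style curvature rule, separated by
  thin boundary sheets broken by periodic bridge voxels.

:func:`inject_pore_noise` adds the pore-type binarization noise used in the
noise-robustness experiments.

Every generator is a pure function of its parameters including the required
``seed``: identical calls return bit-identical bundles.  Foreground /
background intensities default to 200 / 50 on an 8-bit scale, so a global
threshold of 125 recovers the mask exactly when the optional Gaussian
intensity noise is off — binarization is made trivially correct on purpose,
isolating distance-transform and segmentation behavior downstream.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .grids import BinaryMask, IntensityVolume, LabelVolume, PhantomBundle

log = logging.getLogger(__name__)

FOREGROUND_INTENSITY = 200.0
BACKGROUND_INTENSITY = 50.0


def _render_image(mask: np.ndarray, noise_sigma: float, rng: np.random.Generator) -> np.ndarray:
    img = np.where(mask, FOREGROUND_INTENSITY, BACKGROUND_INTENSITY)
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    return img.astype(np.float32)


def _carve_depth(constriction_fraction: float, thickness: int) -> int:
    """Voxels carved into the slab's top face at tile joints.

    The carved depth is the requested fraction of the slab thickness,
    clamped so at least a one-voxel bridge remains against the bottom face.
    """
    depth = int(np.floor(constriction_fraction * thickness))
    return min(depth, thickness - 1)


def _planar_boundary(plane_labels: np.ndarray, single_sided: bool = False) -> np.ndarray:
    """Pixels whose 4-neighborhood holds a different positive label.

    With ``single_sided`` only the higher-label side of each interface is
    marked, giving a one-pixel separating line instead of a two-pixel band.
    """
    lab = plane_labels
    boundary = np.zeros(lab.shape, dtype=bool)
    for axis in (0, 1):
        a = np.take(lab, range(lab.shape[axis] - 1), axis=axis)
        b = np.take(lab, range(1, lab.shape[axis]), axis=axis)
        diff = (a != b) & (a > 0) & (b > 0)
        sl_a = [slice(None)] * 2
        sl_b = [slice(None)] * 2
        sl_a[axis] = slice(0, lab.shape[axis] - 1)
        sl_b[axis] = slice(1, lab.shape[axis])
        if single_sided:
            boundary[tuple(sl_a)] |= diff & (a > b)
            boundary[tuple(sl_b)] |= diff & (b > a)
        else:
            boundary[tuple(sl_a)] |= diff
            boundary[tuple(sl_b)] |= diff
    return boundary


def _extruded_slab_bundle(
    plane_labels: np.ndarray,
    shape: tuple[int, int, int],
    slab_thickness: int,
    constriction_fraction: float,
    rng: np.random.Generator,
    noise_sigma: float,
    params: dict,
    groove_halfwidth: int = 1,
) -> PhantomBundle:
    from scipy import ndimage

    nz, ny, nx = shape
    if slab_thickness > nz:
        raise ValueError(f"slab_thickness {slab_thickness} exceeds z extent {nz}")
    z0 = (nz - slab_thickness) // 2
    z1 = z0 + slab_thickness

    truth = np.zeros(shape, dtype=np.int32)
    truth[z0:z1] = plane_labels[None, :, :]

    mask = truth > 0
    carve = _carve_depth(constriction_fraction, slab_thickness)
    if carve > 0:
        boundary = _planar_boundary(plane_labels)
        if groove_halfwidth > 0:
            boundary = ndimage.binary_dilation(boundary, iterations=groove_halfwidth)
        # single-sided groove: joints narrow toward the top face, the
        # bridge stays against the bottom face (see docs/methods.md)
        mask[z0 : z0 + carve, boundary] = False

    image = _render_image(mask, noise_sigma, rng)
    return PhantomBundle(
        image=IntensityVolume(image),
        truth=LabelVolume(truth),
        mask=BinaryMask(mask),
        params=params,
    )


def voronoi_tiling_phantom(
    shape: tuple[int, int, int] = (16, 128, 128),
    n_tiles: int = 25,
    slab_thickness: int = 12,
    constriction_fraction: float = 0.6,
    seed: int = 0,
    noise_sigma: float = 0.0,
    margin: int = 4,
    lloyd_iterations: int = 3,
    groove_halfwidth: int = 1,
) -> PhantomBundle:
    """A slab of similar-sized Voronoi tiles joined through constrictions.

    ``n_tiles`` sites are drawn uniformly in the slab mid-plane (inset from
    the volume faces by ``margin`` voxels) and regularized by a few Lloyd
    iterations, giving the similar-sized, roundish cells characteristic of
    biological tilings.  Each tile is its planar Voronoi cell extruded
    through the slab.  At inter-tile boundaries a groove of depth
    ``constriction_fraction`` x thickness is carved into the slab's top
    face, so adjacent tiles stay connected only through a bridge against
    the bottom face — a constriction without a resolved boundary.
    ``truth`` keeps the full uncarved cells, so ``mask c= (truth > 0)``
    with equality iff ``constriction_fraction == 0``.
    """
    nz, ny, nx = shape
    if n_tiles < 2:
        raise ValueError("n_tiles must be >= 2")
    if not 0.0 <= constriction_fraction <= 1.0:
        raise ValueError("constriction_fraction must be in [0, 1]")
    inner_area = max(ny - 2 * margin, 0) * max(nx - 2 * margin, 0)
    if inner_area < 9 * n_tiles:
        raise ValueError(
            f"n_tiles={n_tiles} exceeds the voxel budget of a {ny}x{nx} plane "
            "(cells would be under 3 voxels wide)"
        )
    rng = np.random.default_rng(seed)
    yy, xx = np.meshgrid(np.arange(ny) + 0.5, np.arange(nx) + 0.5, indexing="ij")
    inner = (yy >= margin) & (yy <= ny - margin) & (xx >= margin) & (xx <= nx - margin)

    def assign(sites):
        d2 = (yy[..., None] - sites[:, 0]) ** 2 + (xx[..., None] - sites[:, 1]) ** 2
        plane = np.argmin(d2, axis=-1).astype(np.int32) + 1
        plane[~inner] = 0
        return plane

    # rejection-resample until every site owns at least one pixel
    for _ in range(100):
        sites = np.column_stack(
            [rng.uniform(margin, ny - margin, n_tiles),
             rng.uniform(margin, nx - margin, n_tiles)]
        )
        plane = assign(sites)
        if np.unique(plane).size == n_tiles + 1:
            break
    else:  # pragma: no cover - vanishingly unlikely
        raise RuntimeError("could not place non-degenerate Voronoi sites")
    for _ in range(lloyd_iterations):
        for i in range(n_tiles):
            sel = plane == i + 1
            if sel.any():
                sites[i] = [yy[sel].mean(), xx[sel].mean()]
        plane = assign(sites)

    params = {
        "kind": "voronoi",
        "shape": tuple(shape),
        "n_tiles": n_tiles,
        "slab_thickness": slab_thickness,
        "constriction_fraction": constriction_fraction,
        "seed": seed,
        "noise_sigma": noise_sigma,
        "margin": margin,
        "lloyd_iterations": lloyd_iterations,
        "groove_halfwidth": groove_halfwidth,
    }
    return _extruded_slab_bundle(
        plane, shape, slab_thickness, constriction_fraction, rng, noise_sigma,
        params, groove_halfwidth,
    )


def hexagonal_tiling_phantom(
    n_rows: int = 5,
    n_cols: int = 5,
    tile_radius: int = 10,
    slab_thickness: int = 12,
    constriction_fraction: float = 0.5,
    seed: int = 0,
    noise_sigma: float = 0.0,
) -> PhantomBundle:
    """A regular hexagonal tiling extruded through a slab.

    Centers sit on a pointy-top hexagonal lattice (odd rows offset by half a
    column); pixels are assigned to the nearest center, which rasterizes the
    exact hexagonal Voronoi cells.  Every interior tile has exactly six
    touching neighbors in the truth labeling.  Labels are numbered row-major
    from 1.
    """
    if n_rows < 3 or n_cols < 3:
        raise ValueError("n_rows and n_cols must be >= 3 so interior tiles exist")
    if tile_radius < 2:
        raise ValueError("tile_radius must be >= 2 voxels")
    r = float(tile_radius)
    dx = np.sqrt(3.0) * r
    dy = 1.5 * r
    margin = r
    centers = np.array(
        [
            (margin + i * dy, margin + j * dx + (dx / 2 if i % 2 else 0.0))
            for i in range(n_rows)
            for j in range(n_cols)
        ]
    )
    ny = int(np.ceil(centers[:, 0].max() + margin))
    nx = int(np.ceil(centers[:, 1].max() + margin + dx / 2))
    nz = slab_thickness + 4
    yy, xx = np.meshgrid(np.arange(ny) + 0.5, np.arange(nx) + 0.5, indexing="ij")
    d2 = (yy[..., None] - centers[:, 0]) ** 2 + (xx[..., None] - centers[:, 1]) ** 2
    plane = np.argmin(d2, axis=-1).astype(np.int32) + 1
    rng = np.random.default_rng(seed)
    params = {
        "kind": "hex",
        "n_rows": n_rows,
        "n_cols": n_cols,
        "tile_radius": tile_radius,
        "slab_thickness": slab_thickness,
        "constriction_fraction": constriction_fraction,
        "seed": seed,
        "noise_sigma": noise_sigma,
    }
    return _extruded_slab_bundle(
        plane, (nz, ny, nx), slab_thickness, constriction_fraction, rng, noise_sigma, params
    )


def hex_interior_labels(n_rows: int, n_cols: int) -> np.ndarray:
    """Row-major labels of the interior tiles of a hex phantom grid."""
    labels = []
    for i in range(1, n_rows - 1):
        for j in range(1, n_cols - 1):
            labels.append(i * n_cols + j + 1)
    return np.array(labels, dtype=np.int64)


def inject_pore_noise(mask: BinaryMask, pore_rate: float, seed: int) -> BinaryMask:
    """Flip each foreground voxel to background with probability ``pore_rate``.

    Emulates pore-type noise inside otherwise solid structures in a binary
    segmentation; background voxels are never touched.
    """
    if not 0.0 <= pore_rate < 1.0:
        raise ValueError("pore_rate must be in [0, 1)")
    if pore_rate == 0.0:
        return BinaryMask(mask.data.copy(), mask.spacing)
    rng = np.random.default_rng(seed)
    flips = rng.random(mask.shape) < pore_rate
    return BinaryMask(mask.data & ~flips, mask.spacing)


def _weighted_voronoi_plane(
    sites: np.ndarray, weights: np.ndarray, alive: np.ndarray, ny: int, nx: int
) -> np.ndarray:
    """Additively weighted Voronoi labeling: argmin_i (d(p, s_i) - w_i)."""
    yy, xx = np.meshgrid(np.arange(ny) + 0.5, np.arange(nx) + 0.5, indexing="ij")
    d = np.sqrt((yy[..., None] - sites[:, 0]) ** 2 + (xx[..., None] - sites[:, 1]) ** 2)
    cost = d - weights[None, None, :]
    cost[:, :, ~alive] = np.inf
    return np.argmin(cost, axis=-1).astype(np.int32) + 1


def columnar_prism_phantom(
    shape: tuple[int, int, int] = (64, 128, 128),
    n_seeds: int = 50,
    coarsening_rate: float = 8.0,
    seed: int = 0,
    noise_sigma: float = 0.0,
    bridge_spacing: int = 8,
) -> PhantomBundle:
    """Columnar prisms that coarsen along the growth (z) axis.

    Each z slice is an additively weighted planar Voronoi labeling of the
    same ``n_seeds`` sites.  Site weights evolve along z by an explicit
    Euler step of the Hillert-style rule

        dw/dz = coarsening_rate * (1/R_mean(z) - 1/R_i(z)),

    with R_i(z) = sqrt(A_i(z)/pi) from the cell's current area, so
    smaller-than-average cells shrink and eventually vanish (their label
    disappears from later slices) while larger ones grow.  Thin background
    sheets separate adjacent columns in the mask, interrupted every
    ``bridge_spacing`` slices by a full-contact band where the boundary is
    not resolved at all — a discontinuous boundary, which both fuses the
    columns into one connected component and breaks each column into
    stacked segments under zero-persistence segmentation.  ``params['growth_class']`` records
    each surviving-at-start column's ground-truth class ('growing' or
    'shrinking') from the least-squares slope of its simulated radius
    profile, and ``params['true_radius']`` the per-slice radii.
    """
    nz, ny, nx = shape
    if n_seeds < 4:
        raise ValueError("n_seeds must be >= 4")
    rng = np.random.default_rng(seed)
    sites = np.column_stack([rng.uniform(0, ny, n_seeds), rng.uniform(0, nx, n_seeds)])
    # Lloyd-regularize the initial layout: compact, similar-sized columns
    # (rounder cells keep each cross-section single-peaked under the walk)
    yy0, xx0 = np.meshgrid(np.arange(ny) + 0.5, np.arange(nx) + 0.5, indexing="ij")
    for _ in range(6):
        d2 = (yy0[..., None] - sites[:, 0]) ** 2 + (xx0[..., None] - sites[:, 1]) ** 2
        plane0 = np.argmin(d2, axis=-1)
        for i in range(n_seeds):
            sel = plane0 == i
            if sel.any():
                sites[i] = [yy0[sel].mean(), xx0[sel].mean()]
    weights = np.zeros(n_seeds)
    alive = np.ones(n_seeds, dtype=bool)

    truth = np.zeros(shape, dtype=np.int32)
    mask = np.zeros(shape, dtype=bool)
    radii = np.full((n_seeds, nz), np.nan)

    for z in range(nz):
        plane = _weighted_voronoi_plane(sites, weights, alive, ny, nx)
        areas = np.bincount(plane.ravel(), minlength=n_seeds + 1)[1:]
        newly_dead = alive & (areas == 0)
        if newly_dead.any():
            alive = alive & ~newly_dead
            plane = _weighted_voronoi_plane(sites, weights, alive, ny, nx)
            areas = np.bincount(plane.ravel(), minlength=n_seeds + 1)[1:]
        if alive.sum() <= 1:
            warnings.warn(
                "coarsening removed all but one column before the z extent ended",
                stacklevel=2,
            )
        r_i = np.sqrt(areas / np.pi)
        radii[alive, z] = r_i[alive]

        boundary = _planar_boundary(plane, single_sided=True)
        # one-voxel separating sheets, interrupted by periodic full-contact
        # bands along z (discontinuous, unresolved boundaries)
        if z % bridge_spacing == 0:
            carved = np.zeros_like(boundary)
        else:
            carved = boundary

        slice_mask = ~carved
        truth[z] = np.where(slice_mask, plane, 0)
        mask[z] = slice_mask

        # Euler step of the coarsening rule for the surviving sites
        r_alive = r_i[alive]
        r_mean = r_alive.mean()
        dw = coarsening_rate * (1.0 / r_mean - 1.0 / r_alive)
        w = weights[alive]
        weights[alive] = w + dw

    growth_class = {}
    zs = np.arange(nz, dtype=float)
    for i in range(n_seeds):
        present = ~np.isnan(radii[i])
        if present.sum() < 2:
            growth_class[i + 1] = "shrinking"
            continue
        slope = np.polyfit(zs[present], radii[i][present], 1)[0]
        growth_class[i + 1] = "growing" if slope > 0 else "shrinking"

    image = _render_image(mask, noise_sigma, rng)
    params = {
        "kind": "prisms",
        "shape": tuple(shape),
        "n_seeds": n_seeds,
        "coarsening_rate": coarsening_rate,
        "seed": seed,
        "noise_sigma": noise_sigma,
        "bridge_spacing": bridge_spacing,
        "growth_class": growth_class,
        "true_radius": radii,
    }
    return PhantomBundle(
        image=IntensityVolume(image),
        truth=LabelVolume(truth),
        mask=BinaryMask(mask),
        params=params,
    )
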