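# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of `tilewalk`.  It is written for users who need to judge what
the package computes and what its synthetic benchmarks do and do not show.

## The random-walk distance transform

For a binary segmentation with foreground set F, define for every voxel
`v ∈ F` the hitting time `h(v)`: the expected number of steps of a simple
random walk started at `v`, moving at each step to a voxel chosen
uniformly among the in-stencil neighbors, stopped on first arrival at a
background voxel.  Conditioning on the first step gives

    h(v) = 1 + (1/deg(v)) Σ_{u ∈ N(v) ∩ F} h(u),

equivalently `deg(v)·h(v) − Σ_{u ∈ N(v) ∩ F} h(u) = deg(v)` with `h ≡ 0`
outside F.  The system matrix `D − A_FF` is a graph Laplacian restricted
to the foreground: symmetric, positive definite whenever every foreground
component can reach background, which the implementation verifies
explicitly before solving (a component with no absorbing neighbor is an
error, not a silent infinity).

Choices the hitting-time definition leaves open, and what this package
does:

* **Stencil** — default 6-connectivity (face neighbors), selectable 18 or
  26.  The face stencil is the canonical discrete Laplacian and keeps the
  walk isotropic on the grid.
* **Volume border** — default *reflecting*: out-of-volume neighbors are
  removed from the stencil and from `deg(v)`.  Tissue frequently touches
  the scan border, and an absorbing border would fabricate background
  there, distorting the global shape signal.  An *absorbing* border
  (out-of-volume counts as background) is available per `WalkSpec`.
  Note one practical consequence of reflection: voxels on the border have
  smaller degree, hence systematically longer escape times; thin elevated
  rims along the volume faces are expected and real, not artifacts.
* **Step metric** — every step counts 1 regardless of voxel spacing or
  diagonal moves.  The transform is deliberately spacing-free; physical
  anisotropy enters the workflow only through the Euclidean transform and
  the morphometrics.

**Solver.**  Up to 2·10⁵ foreground voxels the system is solved by sparse
LU factorization; above that by conjugate gradients with Jacobi
preconditioning, with the CG tolerance set a factor 10 below the
contractual bound.  Every returned map is verified against the relative
residual bound ‖(D−A)h − d‖/‖d‖ ≤ `solver_tolerance` (default 1e-8); a
violation raises rather than returning a degraded map.  An independent
Monte-Carlo estimator (`monte_carlo_walk_length`) simulates the identical
walk and is used in the test suite to validate the solver on random masks
(solver value within 3 standard errors of a 20 000-walk mean).

**Normalization and the threshold ensemble.**  `minmax_normalize` maps
foreground values affinely onto [0, 1] (a constant map becomes all ones —
a flat field has no contrast to preserve).  `ensemble_rwdt` repeats
binarization + RWDT + normalization over a strictly increasing threshold
ladder and averages voxelwise, dividing by the *total* number of
thresholds: a voxel that is foreground at only a few thresholds is pulled
down, which is exactly what makes threshold-fragile constrictions dip in
the averaged map.  Thresholds whose mask cannot reach background are
skipped (logged) but keep their slot in the denominator; if every
threshold fails, the ensemble fails.

## Contour-tree segmentation with persistence merging

Foreground voxels are swept in strictly decreasing map order, ties broken
by ascending linear (z-major) index, so the sweep is a pure function of
its input.  A voxel with no labeled neighbor founds a region (a maximum,
birth value = its value).  A voxel adjacent to one region joins it.  A
voxel adjacent to k ≥ 2 regions is a saddle: every adjacent region whose
persistence (birth − saddle value) is strictly below the persistence
threshold is merged into the adjacent region with the globally highest
peak, and the voxel joins that region.

One rule deserves emphasis: a region whose birth value *equals* the
current saddle value is always absorbed, regardless of threshold.  Such a
region is a zero-persistence feature — a piece of the same level set
(plateau) reached by the sweep from two sides — not a distinct maximum.
With this rule, threshold 0 performs no merging of distinct maxima and
the label count at threshold 0 equals the plateau-aware local-maximum
count (`count_local_maxima`), while a constant plateau still yields one
label.  Without it, the label count at threshold 0 would depend on the
voxel enumeration order inside plateaus, which is not a property of the
data.

Persistence thresholds are interpreted on the min–max-normalized scale by
default (`normalize_first=True`); the standard working value 0.15 only
makes sense on a bounded scale.  Saddle voxels are always assigned to the
surviving region — there is no unlabeled "watershed line" set, so labels
partition the foreground exactly.

## Euclidean distance transform

`euclidean_distance` wraps the exact Euclidean transform (voxel-center to
voxel-center, optionally scaled by spacing).  It exists as the comparison
baseline: the test suite verifies it against a brute-force all-pairs
oracle on random masks.  Its known failure modes — sensitivity to pore
noise (the shortest escape is destroyed by a single flipped voxel) and
blindness to constrictions that occur in only one spatial dimension — are
what the random-walk transform is designed to avoid.

## Post-processing

`apply_merges` collapses listed label pairs with union semantics (each
connected pair set becomes its smallest member; order-independent).
`directed_merge` automates merging of columnar over-segmentations: two
*touching* labels merge when (a) the angle between their centroid
difference and the growth axis is ≤ `angle_tolerance` (default 30°), (b)
their axis-perpendicular footprints overlap by ≥ `min_overlap_fraction`
(default 0.5, measured against the smaller footprint), and (c) the gap
between their axis extents is ≤ `max_gap` voxels (default 3).  The three
gates encode "merge along growth, never sideways": pieces of one broken
column stack along the axis with near-identical footprints, while distinct
neighboring columns have nearly disjoint footprints however their
centroids align.  The procedure iterates to a fixed point in ascending
label-pair order and is idempotent; neither operation ever changes the
foreground voxel set.  Defaults were chosen for clearly columnar
morphologies (footprint overlap is the discriminating gate; the angle gate
mainly prunes the candidate set) and should be re-examined for stubby or
strongly tilted columns.

## Morphometrics

* Neighbor counts come from the region adjacency graph with *face*
  (6-connectivity) contacts and a minimum contact count (default 1).
  Face contact is the strictest reproducible notion of "touching"; a
  `min_contact` knob covers datasets where single-voxel contacts are
  segmentation noise.
* Per-tile records: voxel count, physical volume, Gaussian-free mean
  intensity (a mineral-density proxy), centroid, and principal extents
  defined as 4·√(eigenvalue) of the physical voxel-coordinate covariance
  — a rotation-invariant full-width proxy (for a uniform axis-aligned box
  it overestimates the true width by ~15%, consistently across tiles).
* Prism profiles: per label and slice along the growth axis, area A(z)
  (voxel count × in-plane voxel area) and R(z) = √(A/π); the growth slope
  is the ordinary least-squares dR/dz over the label's extent, the class
  "growing" iff slope > 0.  *Relative curvature* is the per-label mean of
  `1/R̄(z) − 1/R_i(z)` with R̄(z) the mean radius over the labels present
  in slice z — R̄ standing in for the critical radius of curvature-driven
  (Hillert-type) grain growth, against which larger-than-average columns
  grow and smaller ones shrink.  Labels spanning fewer than two slices get
  a NaN slope and are excluded from trend statistics.
* `evaluate_segmentation` maps each predicted label to its
  majority-overlap truth label; a truth label is matched one-to-one iff
  exactly one predicted label maps to it; truth labels receiving ≥ 2
  predicted labels count as split; predicted labels whose majority covers
  < 60% of their voxels, or that hold the plurality of ≥ 2 truth labels,
  count as merged.

## Synthetic phantoms: what they emulate and what they do not

No public µCT data accompany the method, so every quantitative claim in
the test suite is made on synthetic volumes with exact ground truth.

**Slab tilings** (`voronoi_tiling_phantom`, `hexagonal_tiling_phantom`)
emulate a mineralized tiling in a flat slab: similar-sized planar cells
(Voronoi cells of sites regularized by a few Lloyd iterations, or an
exact hexagonal lattice) extruded through the slab thickness, set off from
the volume faces by a small background margin, and joined at every
inter-tile boundary through a constriction: a groove carved into the slab
along the boundary so that tiles remain connected only through a
continuous bridge — contact without a resolved boundary.  The groove is
carved from one face of the slab (total depth = `constriction_fraction` ×
thickness, clamped to keep at least a one-voxel bridge), leaving the
bridge against the opposite face.  This single-sided geometry mirrors how
tesserae-like tilings meet: wide bodies, narrow contact necks offset
toward one tissue face.  It also makes the benchmark honest in both
directions: the bridge sits between two nearby background reservoirs
(slab face below, groove above), so a random walk crossing a joint is
absorbed quickly (deep, high-persistence tile maxima), while the *minimum*
background distance at the crossing — all the Euclidean transform can see
— stays comparable to the distances pore noise imprints everywhere else.
The truth labeling keeps the full uncarved cells; the mask equals the
truth support minus the grooves.

**Pore noise** (`inject_pore_noise`) flips each foreground voxel
independently with the given probability, emulating segmentation porosity.
The default rate 0.01 is a package choice (the noise level of the
motivating comparison figure is not stated anywhere authoritative).

**Columnar prisms** (`columnar_prism_phantom`) tile each cross-section
with additively weighted Voronoi cells of fixed, Lloyd-regularized sites
whose weights evolve along z by one explicit-Euler step per slice of
dw/dz = rate·(1/R̄ − 1/R_i): smaller-than-average columns shrink and
vanish (their sites are removed permanently), larger ones grow — the
qualitative content of curvature-driven coarsening.  Columns are
separated by one-voxel background sheets, interrupted every
`bridge_spacing` slices (default 8) by a full-contact band where the
boundary is not resolved at all.  The bands make the whole layer one
connected component and, under zero-persistence segmentation, break each
column into stacked segments with near-identical footprints — the
over-segmentation pattern that growth-directed merging repairs.  Site
regularization matters here: rounder cells keep each cross-section
single-peaked under the walk, so columns split transversely (along z)
rather than lengthwise, which directed merging deliberately refuses to
repair.  The default rate 8.0 makes a 50-column, 128²-plane, 64-slice
phantom lose a visible fraction of its columns while keeping per-slice
radii well resolved; the recorded ground-truth class of each column is
the sign of the least-squares slope of its simulated radius profile.
Across phantom seeds the slope-vs-relative-curvature correlation among
shrinking columns typically falls in the 0.75–0.95 range; the spread
comes from voxelization noise on small cells and from the nonlinearity of
the rule as R̄ drifts.

What the phantoms deliberately do **not** model: curved anatomical
surfaces (and therefore the below-six mean neighbor counts of closed
tilings), beam hardening and reconstruction artifacts, correlated
(blob-like) segmentation noise, intensity gradients within tiles, and
partial-volume effects.  Passing the phantom benchmarks therefore shows
that the transform/segmentation machinery behaves as designed in the
constriction-plus-pore-noise regime; it does not certify performance on
any particular scanner's data.

## Numerical and degenerate-input policy

* Local normalization uses Gaussian-windowed moments with
  σ_w = √(max(E[I²]−E[I]², 0)) to absorb floating-point cancellation, and
  rejects window scales that reach the volume extent (the neighborhood
  must be local).
* Thresholding takes foreground as intensity ≥ threshold (bright
  mineralized tissue), with an invert flag for dark-foreground data.
* All-background masks are errors for the RWDT (nothing to measure) and
  for segmentation; the EDT of an empty foreground is an all-zero map.
* Phantom generators are pure functions of their parameter records
  including the mandatory seed; all randomness flows through
  `numpy.random.default_rng(seed)`, and identical calls are bit-identical.
* Workflow runs write a manifest echoing the exact configuration; because
  every stage is deterministic given the manifest, a run can be reproduced
  bit-exactly from the manifest alone.

## Problem sizes in the shipped benchmarks

The test suite and the acceptance script run entirely on phantoms sized
for a single CPU: the noise-robustness experiment uses a 16×128×128 slab
with 25 tiles (~1.6·10⁵ foreground voxels, solved by CG), the hexagonal
benchmark a 5×5 grid, and the coarsening benchmark 50 columns on a
64×128×128 grid.  These sizes were chosen as the smallest at which the
studied effects are cleanly expressed; the library itself has no
phantom-specific assumptions and the solver path switches automatically
for larger volumes.
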