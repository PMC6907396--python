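# tilewalk

High-throughput segmentation and morphometrics for **tiled biological
structures** in 3D grayscale volumes — tessellated cartilage tiles
(tesserae), echinoderm dermal ossicles, prismatic mollusc-shell columns,
and similar repeating units that are in direct contact and therefore cannot
be separated by thresholding alone.

The core of the package is the **random-walk distance transform (RWDT)**:
for every foreground voxel `v` of a binary segmentation, the expected
number of steps `h(v)` of a simple random walk on the voxel grid until it
first reaches a background voxel.  By first-step analysis, `h` is the
unique solution of the absorbing-walk linear system

```
deg(v) · h(v) − Σ_{u ∈ N(v) ∩ FG} h(u) = deg(v),      h ≡ 0 on background,
```

where `N(v)` is the walk stencil (6/18/26-neighborhood) and `deg(v)` the
number of in-stencil neighbors.  The matrix is a symmetric
positive-definite graph Laplacian restricted to the foreground and is
solved sparsely (direct factorization, or preconditioned conjugate
gradients for large volumes).  Unlike the Euclidean distance transform
(EDT), which measures only the single shortest escape, `h` averages over
*all* escape routes: it reflects the global shape of an object, detects
constrictions in any single spatial dimension (including flat objects),
and barely moves under pore-type noise in the binary segmentation.

On top of the transform, the package provides the full workflow:

1. **pre-processing** — Gaussian-windowed local mean/variance
   normalization (`local_normalize`);
2. **binary segmentation** — global thresholding and small-component
   removal (`threshold_mask`, `remove_small_components`);
3. **distance transform** — `random_walk_distance`, the exact
   `euclidean_distance` for comparison, min–max normalization, and the
   multi-threshold `ensemble_rwdt` (average of normalized RWDTs over a
   threshold ladder);
4. **over-segmentation** — contour-tree region growing from local maxima
   with topological-persistence merging (`contour_tree_segment`), where a
   single threshold controls the degree of merging;
5. **post-processing** — manual merge lists (`apply_merges`) and automatic
   directed merging along a growth axis (`directed_merge`);
6. **quantification** — region adjacency graphs, per-tile volume /
   neighbor-count / intensity statistics, per-column radius profiles
   `R(z) = √(A/π)` with Hillert-style growth/shrink classification, and
   overlap-based evaluation against ground truth.

Because no public µCT data accompany the method, `tilewalk.phantoms`
generates synthetic volumes with exact ground truth: slab tilings of
similar-sized units joined by unresolved constrictions, hexagonal tilings
(every interior tile has six neighbors), and columnar prisms coarsening
along their growth axis, plus pore-type binarization noise.

## Worked example

```
$ python examples/02_noise_robust_segmentation.py
phantom: 25 tiles, 149406 foreground voxels (1480 pores injected)
clean-vs-noisy rank correlation:  RWDT 0.962   EDT 0.774
  (the RWDT field barely moves under pores; the EDT field scrambles)
RWDT + persistence 0.15: 25 labels, 25/25 matched one-to-one
EDT, best over a 20-point persistence grid: 17/25 matched (no threshold fixes the noise-induced errors)
```

The phantom has 25 tiles; after 1% of foreground voxels are flipped to
pores, the RWDT pipeline still recovers all 25 tiles one-to-one at the
standard persistence threshold 0.15 (on the min–max-normalized map), while
the EDT pipeline cannot reach a perfect segmentation at *any* merge
threshold — the pores create spurious maxima whose persistence overlaps
that of true tiles.

Other examples: `examples/01_rwdt_basics.py` (hand-solvable walk systems
and the Monte-Carlo oracle), `examples/03_neighbor_morphometrics.py`
(hexagonal neighbor counts), `examples/04_prism_coarsening.py`
(curvature-driven coarsening of columns).

## Command line

Every stage is also a subcommand of the `tilewalk` CLI (`normalize`,
`binarize`, `clean`, `rwdt`, `edt`, `ensemble`, `segment`, `merge`,
`merge-directed`, `quantify`, `prisms`, `evaluate`, `phantom`, `run`).
`tilewalk run config.yaml --out-dir RUN` executes a whole configured
workflow and writes every intermediate volume plus a manifest that
reproduces the run bit-exactly.  Volumes are read and written as multipage
TIFF, directories of 2D slices, or NRRD.

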