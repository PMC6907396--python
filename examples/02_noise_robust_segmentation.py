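"""Noise robustness: RWDT vs Euclidean distance on a tiled slab phantom.

Generates a slab of Voronoi tiles joined by constrictions, corrupts the
binary mask with 1% pore noise, segments with both distance transforms,
and scores each against the known ground truth.  The RWDT pipeline should
recover every tile one-to-one; the Euclidean pipeline degrades because
pores destroy its shallow local maxima structure.
"""

import numpy as np
from scipy.stats import spearmanr

from tilewalk import (
    SegmentationParams,
    contour_tree_segment,
    euclidean_distance,
    evaluate_segmentation,
    inject_pore_noise,
    random_walk_distance,
    voronoi_tiling_phantom,
)

bundle = voronoi_tiling_phantom(shape=(16, 128, 128), n_tiles=25, seed=7)
noisy = inject_pore_noise(bundle.mask, pore_rate=0.01, seed=107)
print(f"phantom: {bundle.truth.n_labels} tiles, "
      f"{bundle.mask.foreground_count} foreground voxels "
      f"({bundle.mask.foreground_count - noisy.foreground_count} pores injected)")

rw_clean = random_walk_distance(bundle.mask)
rw_noisy = random_walk_distance(noisy)
shared = bundle.mask.data & noisy.data
rho_rw = spearmanr(rw_clean.data[shared], rw_noisy.data[shared]).statistic

ed_clean = euclidean_distance(bundle.mask)
ed_noisy = euclidean_distance(noisy)
rho_ed = spearmanr(ed_clean.data[shared], ed_noisy.data[shared]).statistic
print(f"clean-vs-noisy rank correlation:  RWDT {rho_rw:.3f}   EDT {rho_ed:.3f}")
print("  (the RWDT field barely moves under pores; the EDT field scrambles)")

labels_rw = contour_tree_segment(rw_noisy, SegmentationParams(persistence_threshold=0.15))
rep = evaluate_segmentation(labels_rw, bundle.truth)
print(f"RWDT + persistence 0.15: {labels_rw.n_labels} labels, "
      f"{rep.n_matched_one_to_one}/25 matched one-to-one")

best = 0
for p in np.linspace(0.0, 0.95, 20):
    labels_ed = contour_tree_segment(ed_noisy, SegmentationParams(float(p)))
    r = evaluate_segmentation(labels_ed, bundle.truth)
    best = max(best, r.n_matched_one_to_one)
print(f"EDT, best over a 20-point persistence grid: {best}/25 matched "
      "(no threshold fixes the noise-induced errors)")
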