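"""Curvature-driven coarsening of columnar prisms.

Generates a columnar phantom whose cross-sections evolve along the growth
axis by a Hillert-style rule (smaller-than-average columns shrink and
vanish, larger ones grow), then recovers the radius profiles R(z) =
sqrt(A/pi) per column and checks the growth/shrink classification and the
rate-vs-relative-curvature trend.
"""

import numpy as np
from scipy.stats import pearsonr

from tilewalk import columnar_prism_phantom, prism_profiles

bundle = columnar_prism_phantom(shape=(64, 128, 128), n_seeds=50,
                                coarsening_rate=8.0, seed=1)
survivors = np.unique(bundle.truth.data[-1])
print(f"50 columns seeded; {len(survivors[survivors > 0])} survive to the last slice")

profiles = [p for p in prism_profiles(bundle.truth) if np.isfinite(p.slope)]
classes = bundle.params["growth_class"]
agree = sum(p.growth_class == classes[p.label] for p in profiles)
print(f"growth/shrink classification matches the generating rule for "
      f"{agree}/{len(profiles)} columns")

shrinking = [p for p in profiles if p.growth_class == "shrinking"]
slopes = [p.slope for p in shrinking]
curv = [p.relative_curvature for p in shrinking]
r = pearsonr(curv, slopes).statistic
print(f"{len(shrinking)} shrinking columns: Pearson r(slope, relative curvature) = {r:.3f}")
print("  (positive: columns with more negative relative curvature shrink faster,")
print("   the linear trend expected from curvature-driven grain growth)")
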