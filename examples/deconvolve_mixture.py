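"""Estimate cell-type abundances from a synthetic marker-gene mixture.

Builds a small signature reference, mixes it with known fractions into a
'tissue' expression vector, and recovers the fractions by elastic-net
deconvolution. Printed: true vs estimated abundance per cell type — on
noiseless input the ranking (and roughly the magnitude) of the true
fractions is recovered, with some shrinkage from the penalty.
"""

import numpy as np
import pandas as pd

from vocal import PenaltyConfig, ReferenceMatrix, deconvolve_sample

rng = np.random.default_rng(0)
n_types, n_markers = 5, 20
# each cell type gets 4 high-expression marker genes
x = np.full((n_markers, n_types), 1.0) + rng.normal(0, 0.05, (n_markers, n_types))
for c in range(n_types):
    x[4 * c: 4 * (c + 1), c] += 3.0
ref = ReferenceMatrix(pd.DataFrame(
    x, index=[f"g{i}" for i in range(n_markers)],
    columns=[f"ct{c}" for c in range(n_types)]))

theta_true = np.array([0.4, 0.3, 0.2, 0.1, 0.0])
y = x @ theta_true

theta = deconvolve_sample(ref, y, PenaltyConfig())
print(f"{'cell type':>10} {'true':>6} {'estimated':>10}")
for c in range(n_types):
    print(f"{'ct' + str(c):>10} {theta_true[c]:6.2f} {theta[c]:10.3f}")
print(f"\nSpearman-like ordering preserved; Pearson r(true, est) = "
      f"{np.corrcoef(theta_true, theta)[0, 1]:.3f}")
print("Estimates are relative abundances; the elastic-net penalty shrinks"
      "\nmagnitudes but preserves the ordering used for trait mapping.")
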