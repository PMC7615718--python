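"""Generate a synthetic pulsatile velocity-field series with ground truth.

Builds the default dataset: 10 cardiac cycles x 18 snapshots at 22 Hz on a
vessel-arc mask, three planted coherent modes driven at 1.22 Hz and its
harmonics, Gaussian noise and 2% spurious vectors.
"""

import numpy as np

from rpodflow import SyntheticFlowSpec, generate_synthetic_flow

spec = SyntheticFlowSpec(rng_seed=0)
series, truth = generate_synthetic_flow(spec)

print(f"grid: {spec.grid_ny} x {spec.grid_nx}, valid points n = {series.n_points}")
print(f"snapshots m = {series.n_snapshots} ({spec.n_cycles} cycles x {spec.snapshots_per_cycle})")
print(f"peak speed: {series.speed().max():.3f} m/s")
print(f"planted singular values: {spec.singular_values_true}")
print(f"spurious vectors: {truth.outlier_mask.sum()} of {truth.outlier_mask.size} components")

# the planted factorisation is exact: mean + modes @ coefficients
stacked = np.vstack([truth.clean_series.u, truth.clean_series.v])
rebuilt = truth.true_mean[:, None] + truth.true_modes @ truth.true_coefficients
print(f"ground-truth factorisation residual: {np.abs(stacked - rebuilt).max():.2e}")
# Expected: m = 180, factorisation residual at machine precision — every
# downstream decomposition can be checked against this known structure.
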