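"""Snapshot POD of a pulsatile series: modal energies and coefficient spectra.

The singular values sigma_i of the 2n x m fluctuation matrix rank the flow's
coherent structures by kinetic energy (lambda_i = sigma_i^2); the temporal
coefficients a_i(t) show how each structure beats with the cardiac cycle.
"""

from rpodflow import (
    SyntheticFlowSpec,
    build_snapshot_matrix,
    coefficient_spectrum,
    generate_synthetic_flow,
    pod,
)

series, _ = generate_synthetic_flow(SyntheticFlowSpec(rng_seed=0))
basis = pod(build_snapshot_matrix(series))

print(f"N = {basis.N} modes from m = {series.n_snapshots} snapshots")
print("mode  sigma_i   E_i      cumulative")
cum = 0.0
for i in range(5):
    cum += basis.fractions[i]
    print(f"{i+1:4d}  {basis.sigma[i]:7.3f}  {basis.fractions[i]:.4f}   {cum:.4f}")

for i in range(3):
    res = coefficient_spectrum(basis.coefficients[i], series.sample_rate)
    print(f"a_{i+1}(t) spectral peak: {res.peak_freq:.3f} Hz")
# Expected: the first two modes carry ~90% of the fluctuation energy and the
# leading coefficients peak at the cardiac frequency (1.22 Hz) and its
# harmonics (2.44, 3.67 Hz) — the signature of cycle-locked pulsatile flow.
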