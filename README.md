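# rpodflow

Robust reduced-order modelling of time-resolved 2D velocity fields, aimed at
experimental cardiovascular flows (PIV of pulsatile flow in vessel phantoms)
but applicable to any gridded (u, v) snapshot series.  The package combines:

- **RPCA de-noising** — split the 2n × m velocity stack into a low-rank
  coherent part **L** and a sparse part **S** (spurious vectors) by solving
  the convex program

      min ‖L‖\* + λ₀‖S‖₁  subject to  U = L + S,   λ₀ = λ₁/√max(m, n),

  with an inexact augmented-Lagrange-multiplier / alternating-direction
  solver (singular-value thresholding + soft shrinkage);
- **snapshot POD** — economy SVD of the mean-subtracted fluctuation matrix,
  U = ΦΣΨ\*, giving energy-ranked orthonormal spatial modes Φᵢ, modal
  energies λᵢ = σᵢ², energy fractions Eᵢ = λᵢ/Σλ, and temporal coefficients
  aᵢ(t) = σᵢΨᵢ\*;
- **truncated ROMs** — Uᵣ = ΦᵣΣᵣΨᵣ\* with the mean flow re-added, scored by
  cumulative energy and the relative ℓ1 reconstruction error
  ε = Σ|U − Uᵣ| / Σ|U| × 100%;
- **spectral analysis** of the temporal coefficients (one-sided amplitude
  spectra; pulsatile flow shows the cardiac fundamental and its harmonics);
- a **synthetic pulsatile-flow generator** with planted modes, singular
  values and harmonic time courses, so every stage can be validated against
  known ground truth.

## Worked example

```python
from rpodflow import (SyntheticFlowSpec, generate_synthetic_flow,
                      build_snapshot_matrix, pod, denoised_snapshot_matrix,
                      cumulative_energy_table)

series, truth = generate_synthetic_flow(SyntheticFlowSpec(rng_seed=0))
sm = build_snapshot_matrix(series)          # 472 x 180 fluctuation matrix
plain = pod(sm)                             # POD of the noisy data
filtered, dec = denoised_snapshot_matrix(sm)  # RPCA: U = L + S
robust = pod(filtered)                      # RPOD: POD of L
print(cumulative_energy_table(robust).to_string(index=False))
```

prints

```
modes  energy_pct    error_pct
  1-2   96.974796 1.230172e+01
  1-5   99.972935 1.253024e+00
 1-10   99.977725 1.133363e+00
  all  100.000000 2.964825e-13
```

Reading: the two leading robust modes already hold 97.0% of the fluctuation
kinetic energy (vs 90.7% for POD of the raw noisy series), five modes
reconstruct the de-noised flow to 1.3% ℓ1 error, and keeping every mode
reproduces it exactly — the `all` row is the full-order model.  The RPCA
diagnostics (`dec.rank_L = 106` of 180 snapshots, `dec.nnz_S`) quantify how
much structure was compressed into L and how many entries were flagged as
sparse corruption.

The `examples/` directory has one short script per capability (generation,
POD + spectra, RPCA, ROM tables, the full pipeline); each prints the numbers
it computes and what they mean.  The same workflow is scriptable from the
shell:

```sh
rpodflow synth --out data --fmt npz
rpodflow rpca data/series.npz --out LS.npz
rpodflow reconstruct data/series.npz --modes 10
rpodflow run --config cfg.yaml --seed 1 --out rundir
```

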