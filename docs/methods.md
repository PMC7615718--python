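# Methods

## Problem setting

Time-resolved planar velocimetry of pulsatile flow — e.g. PIV of a vessel
phantom — yields m snapshots of a 2D velocity field (u, v) on a fixed
Cartesian grid, of which n points lie inside the lumen.  The flow is
dominated by a few coherent structures locked to the cardiac cycle, but the
measurements carry Gaussian noise and a sparse population of spurious
vectors from failed image correlations.  rpodflow extracts the coherent
structures (robustly), builds truncated reduced-order models, and
quantifies what each truncation keeps and loses.

## Data model and snapshot matrix

Only valid grid points are stored.  The time-averaged velocity is computed
per point over **all** m snapshots (all cycles pooled, which suppresses
single-cycle bias) and subtracted; fluctuations are stacked into the
2n × m snapshot matrix U with the u-block above the v-block, grid points
scanned row-major (y-outer, x-inner).  Masked points are **excluded** from
U rather than zero-filled — zero-filling would deflate modal energies — and
the mask is carried alongside so fields can be re-embedded for plotting and
export.  Coordinates are metres, velocities m/s, indexing 0-based.

## RPCA de-noising

The corrupted stack is modelled as U = L + S with L low-rank (coherent
flow, including the mean) and S sparse (spurious vectors).  The convex
relaxation

    min ‖L‖* + λ₀‖S‖₁   s.t.  U = L + S

is solved by inexact augmented Lagrange multipliers with alternating
proximal updates: soft shrinkage at λ₀/μ for S, singular-value thresholding
at 1/μ for L, dual update Y ← Y + μ(U − L − S), penalty growth μ ← ρμ.

Parameter choices (all overridable):

| parameter | default | why |
|---|---|---|
| λ₁ | 1 | classical weight; raising it empties S, lowering it shrinks rank(L) |
| λ₀ form | λ₁/√max(m, n) | the form with recovery guarantees; a linear form λ₁/max(m, n) is selectable, as is a direct λ₀ |
| μ₀ | 1.25/σ₁(U) | standard well-conditioned initialisation |
| ρ | 1.1 | measured on planted low-rank + sparse instances: aggressive growth (ρ ≈ 1.5) reaches feasibility quickly but freezes the iterates at a suboptimal point (objective gap ~10⁻⁴ relative, low-rank recovery ~10⁻²); ρ = 1.1 tracks the optimum of the convex program (gap < 10⁻⁸, recovery ~10⁻⁹) at roughly 3× the sweeps, still ~100 iterations / about a second on a 472 × 180 stack |
| tol | 1e-7 | relative Frobenius feasibility ‖U−L−S‖F/‖U‖F; exhaustion of max_iter (500) returns `converged=False` rather than raising |

RPCA is applied to the **raw, mean-included** stack; the mean flow is then
recomputed from L and subtracted before POD.  This matches the workflow
order (de-noise the measured field, then decompose) and lets S absorb the
full magnitude of a spurious vector rather than only its fluctuation part.
All SVDs are deterministic economy decompositions — no randomised sketching
— so results are bit-reproducible.

## Snapshot POD and ROMs

POD is the economy SVD of the fluctuation matrix.  The reported mode count
N is capped at the numerical rank (σᵢ > 10⁻¹² σ₁), so numerically null
modes are never listed — the de-noised stack genuinely has far fewer modes
than snapshots.  Each (Φᵢ, Ψᵢ) pair is sign-normalised so the
largest-magnitude entry of Φᵢ is positive; reconstructions and energies are
invariant to this choice, but it makes modes reproducible across SVD
backends.

The r-mode ROM is Uᵣ = ΦᵣΣᵣΨᵣ* plus the mean.  Two error conventions are
implemented because either is defensible: the default sums |·| over the
**mean-restored** velocity matrices (errors are then relative to the actual
flow field a practitioner sees); `include_mean=False` sums over
fluctuations only.  The Frobenius truncation error is non-increasing in r
(Eckart–Young); the ℓ1 metric is reported as-is and is only guaranteed ~0
at r = N, which the tests pin.

Coefficient spectra use the raw (unwindowed) series by default — coefficient
time courses of cycle-locked acquisitions are already near-periodic over the
record — with a Hann window behind a flag.  Amplitudes are calibrated so an
on-bin tone of amplitude A reports A; the peak search excludes the DC bin.

## Synthetic generator

The generator emulates the statistical structure the analysis assumes, with
the low-rank part planted exactly:

- **shape**: 10 cycles × 18 snapshots = 180 frames at 22 Hz, cardiac
  fundamental 1.22 Hz (the sampling is cycle-locked: 22/18 ≈ 1.222 Hz), on
  a 20 × 20 grid masked to a curved vessel-like band (236 valid points);
- **spatial modes**: smooth separable trigonometric patterns on the masked
  grid, orthonormalised by modified Gram–Schmidt over the stacked (u, v)
  representation — smoothness mimics large-scale coherent structures;
- **temporal coefficients**: mode i carries configured harmonics of the
  cardiac frequency (default: harmonic i, so mode 2 beats at 2.44 Hz); the
  sampled signals are mean-centred and Gram–Schmidt orthonormalised so the
  clean fluctuation matrix has singular values *exactly*
  `singular_values_true` — parameter-recovery tests compare against exact
  ground truth, not approximations;
- **mean flow**: `mean_flow_scale` × the first spatial pattern (the most
  energetic structure of pulsatile arterial flow is organised motion aligned
  with the mean), default scale 5 giving ~1 m/s peak speeds;
- **noise**: additive Gaussian (default sd 0.01 m/s, percent-level) plus
  `outlier_fraction` (default 2%) of the 2n·m components **replaced** by
  uniform ±0.3 m/s draws — replacement, not addition, is how a failed
  correlation behaves.  Default fluctuation singular values (50, 25, 10)
  put fluctuation energy on the order of the mean-flow energy, so the raw
  series behaves like measurement-grade pulsatile PIV: POD of the noisy
  data needs ~10 modes for what robust POD captures in 2.

One `rng_seed` drives all randomness through deterministically spawned
sub-streams; identical specs give bit-identical series.

What the generator does **not** emulate: spatially correlated PIV noise,
cycle-to-cycle waveform variability, turbulence cascades, wall compliance,
or 3D/out-of-plane effects.  Tests passing on synthetic data therefore
demonstrate correctness of the decomposition machinery and robustness to
the modelled noise families — not performance on every real acquisition.

## Pipeline

`run_pipeline` executes acquire → (RPCA) → POD → ROM/report with per-stage
structured logging and stage-tagged error propagation.  Reports carry a
16-hex-digit SHA-256 content hash of the configuration, package versions
and the seed; identical config + seed reproduces the report bit for bit.
Figures are best-effort (a plotting failure never fails a run — the tables
are the contract).  Per-instant reconstruction differences (max absolute
speed difference at configurable snapshot indices, systole/diastole
analogues) are taken against the analysed field: the RPCA-filtered
full-order model when de-noising is on, the raw one otherwise.

## Problem sizes

Tests and the acceptance script use the full 180-snapshot study shape on
20 × 20 (472 × 180 stacks) for end-to-end properties, 10 × 10 grids with 2–3
cycles for unit-level checks, and 40 × 30 planted matrices for solver
optimality, where the reference optimum comes from an independently written
Douglas–Rachford splitting solver of the same convex program.  The whole
suite runs in a few seconds on one CPU.

## Known limitations

- No partial-observation (matrix completion) or streaming RPCA; corrupted
  entries must be in-frame.
- λ₁ is a genuine tuning parameter: too low over-filters coherent motion,
  too high lets noise through; the package exposes it everywhere but does
  not auto-tune it.
- The ℓ1 error metric is not monotone in r in general (only the Frobenius
  truncation error is), so adding modes can occasionally raise the reported
  percentage — visible in noisy tables at large r.
- Masked-point handling (exclusion) assumes the mask is static across the
  series; time-varying masks are rejected at load.
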