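"""RPCA de-noising: split a corrupted velocity stack into low-rank + sparse.

Solves min ||L||_* + lambda0 ||S||_1 s.t. U = L + S by inexact augmented
Lagrange multipliers.  L captures the coherent flow; S absorbs spurious
vectors.  POD of L concentrates energy in far fewer modes than POD of the
raw data — the robust-POD (RPOD) effect.
"""

from rpodflow import (
    SyntheticFlowSpec,
    build_snapshot_matrix,
    denoised_snapshot_matrix,
    generate_synthetic_flow,
    pod,
)

series, _ = generate_synthetic_flow(SyntheticFlowSpec(rng_seed=0))
sm = build_snapshot_matrix(series)

plain = pod(sm)
filtered, dec = denoised_snapshot_matrix(sm)
robust = pod(filtered)

print(f"RPCA: converged={dec.converged} in {dec.iterations} iterations, "
      f"residual {dec.residual:.1e}")
print(f"rank(L) = {dec.rank_L} (vs {sm.m} snapshots); "
      f"S has {dec.nnz_S}/{dec.S.size} nonzeros")
print(f"cumulative E1-2:  raw POD {plain.fractions[:2].sum():.4f}   "
      f"RPOD {robust.fractions[:2].sum():.4f}")
# Expected: the low-rank part has rank well below the snapshot count, and
# the two leading RPOD modes capture a visibly larger energy share than the
# same modes of the noisy data — de-noising concentrates kinetic energy.
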