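"""Independent oracles for the RPCA convex program.

The Douglas–Rachford splitting solver here shares no code or algorithmic
structure with the package's inexact-ALM implementation: it iterates the
exact proximal maps of the objective ``||L||_* + lam0 ||S||_1`` and the
projection onto the affine constraint ``L + S = U``, which converges to the
global optimum of the convex program for any step size.  It is deliberately
slow and simple — a ground-truth reference for small instances only.
"""

from __future__ import annotations

import numpy as np


def _svt(M: np.ndarray, tau: float) -> np.ndarray:
    W, s, Vt = np.linalg.svd(M, full_matrices=False)
    return (W * np.maximum(s - tau, 0.0)) @ Vt


def _shrink(M: np.ndarray, tau: float) -> np.ndarray:
    return np.sign(M) * np.maximum(np.abs(M) - tau, 0.0)


def rpca_objective(L: np.ndarray, S: np.ndarray, lam0: float) -> float:
    return float(np.linalg.svd(L, compute_uv=False).sum() + lam0 * np.abs(S).sum())


def rpca_douglas_rachford(
    U: np.ndarray,
    lam0: float,
    step: float | None = None,
    max_iter: int = 20000,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve min ||L||_* + lam0 ||S||_1 s.t. L + S = U by Douglas–Rachford.

    Splitting: g = indicator of the affine constraint (prox = orthogonal
    projection), f = the separable objective (prox = singular-value
    thresholding on the L block, soft shrinkage on the S block).  Returns
    the feasible iterate (L, S) with L + S = U exactly.
    """
    U = np.asarray(U, dtype=float)
    if step is None:
        step = max(np.linalg.norm(U, 2) / 4.0, 1e-12)
    zL = U / 2.0
    zS = U / 2.0
    xL = xS = None
    for _ in range(max_iter):
        # x = proj onto {L + S = U}
        r = (zL + zS - U) / 2.0
        xL, xS = zL - r, zS - r
        # y = prox_{step f}(2x - z)
        yL = _svt(2 * xL - zL, step)
        yS = _shrink(2 * xS - zS, step * lam0)
        dL, dS = yL - xL, yS - xS
        zL += dL
        zS += dS
        if np.sqrt(np.linalg.norm(dL) ** 2 + np.linalg.norm(dS) ** 2) <= tol * max(
            1.0, np.linalg.norm(U)
        ):
            break
    r = (zL + zS - U) / 2.0
    return zL - r, zS - r


def planted_instance(
    shape: tuple[int, int] = (40, 30),
    rank: int = 2,
    sparse_fraction: float = 0.1,
    outlier_scale: float = 5.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random low-rank L0 plus sparse S0 with entries ~outlier_scale x typical.

    Returns (U, L0, S0) with U = L0 + S0 and disjoint bookkeeping: S0 is
    zero off its support.
    """
    rng = np.random.default_rng(seed)
    m, n = shape
    A = rng.standard_normal((m, rank))
    B = rng.standard_normal((n, rank))
    L0 = A @ B.T
    typical = np.abs(L0).mean()
    S0 = np.zeros((m, n))
    k = int(round(sparse_fraction * m * n))
    idx = rng.choice(m * n, size=k, replace=False)
    S0.flat[idx] = outlier_scale * typical * rng.choice([-1.0, 1.0], size=k)
    return L0 + S0, L0, S0
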