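"""Robust PCA by inexact Augmented Lagrange Multipliers.

Splits a data matrix U into a low-rank part L (coherent flow) and a sparse
part S (spurious vectors / impulsive noise) by solving the convex program

    min  ||L||_* + lambda0 * ||S||_1   subject to  U = L + S,

where ``||.||_*`` is the nuclear norm (sum of singular values) and
``||.||_1`` the elementwise l1 norm.  The weight is

    lambda0 = lambda1 / sqrt(max(m, n))       (default form)

with ``lambda1 = 1`` the classical choice; raising lambda1 pushes more of U
into L (sparser S), lowering it produces a lower-rank L.  A non-square-root
form ``lambda1 / max(m, n)`` is selectable, and lambda0 can be set directly.

The solver is the inexact ALM iteration with alternating-direction prox
updates: the l1 term is minimised by elementwise soft shrinkage, the nuclear
term by singular-value thresholding, and the multiplier/penalty are updated
each sweep.  All SVDs are full economy decompositions — the snapshot
matrices this package targets are at most thousands by hundreds — so the
result is deterministic for fixed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DataError, ValidationError

__all__ = [
    "RPCAParams",
    "RPCADecomposition",
    "rpca_decompose",
    "singular_value_threshold",
    "soft_shrink",
    "effective_rank",
]


def soft_shrink(M: np.ndarray, tau: float) -> np.ndarray:
    """Elementwise soft threshold ``sign(x) * max(|x| - tau, 0)``.

    The proximal operator of ``tau * ||.||_1``; produces exact zeros inside
    the dead zone ``|x| <= tau``.
    """
    if tau < 0:
        raise ValidationError("tau must be >= 0")
    M = np.asarray(M, dtype=float)
    return np.sign(M) * np.maximum(np.abs(M) - tau, 0.0)


def singular_value_threshold(
    M: np.ndarray, tau: float, return_rank: bool = False
) -> np.ndarray | tuple[np.ndarray, int]:
    """Soft-threshold the singular values of ``M`` at ``tau``.

    The proximal operator of ``tau * ||.||_*``: computes the economy SVD
    ``M = W diag(s) V*`` and returns ``W diag(max(s - tau, 0)) V*``.  With
    ``return_rank=True`` also returns the number of singular values that
    survive the shrinkage.
    """
    if tau < 0:
        raise ValidationError("tau must be >= 0")
    M = np.asarray(M, dtype=float)
    if not np.isfinite(M).all():
        raise DataError("non-finite entries in input matrix")
    W, s, Vt = np.linalg.svd(M, full_matrices=False)
    s_shr = np.maximum(s - tau, 0.0)
    rank = int(np.count_nonzero(s_shr))
    out = (W[:, :rank] * s_shr[:rank]) @ Vt[:rank]
    if rank == 0:
        out = np.zeros_like(M)
    return (out, rank) if return_rank else out


def effective_rank(singular_values: np.ndarray, rel_tol: float = 1e-12) -> int:
    """Count singular values above ``rel_tol`` times the largest.

    An all-zero spectrum has rank 0.  Input must be sorted non-increasing.
    """
    s = np.asarray(singular_values, dtype=float)
    if s.size == 0:
        return 0
    if np.any(s < 0):
        raise ValidationError("singular values must be non-negative")
    if np.any(np.diff(s) > 0):
        raise ValidationError("singular values must be sorted non-increasing")
    if s[0] == 0:
        return 0
    return int(np.count_nonzero(s > rel_tol * s[0]))


@dataclass
class RPCAParams:
    """Tuning and solver parameters for :func:`rpca_decompose`.

    Attributes
    ----------
    lambda1
        Sparsity/rank trade-off multiplier; 1 is the classical weight.
    lambda0
        Direct override of the effective l1 weight; when None it is derived
        from ``lambda1`` via ``lambda0_form``.
    lambda0_form
        ``"sqrt"`` -> lambda1/sqrt(max(m, n)); ``"linear"`` -> lambda1/max(m, n).
    tol
        Relative Frobenius feasibility tolerance ``||U-L-S||_F / ||U||_F``.
    max_iter
        Iteration cap; hitting it sets ``converged=False``, never raises.
    mu0, rho
        Initial augmented-Lagrangian penalty (auto ``1.25/sigma1(U)`` when
        None) and its growth factor per sweep.  A modest growth factor
        (default 1.1) lets the iterates track the true optimiser of the
        convex program; aggressive growth reaches feasibility in fewer
        sweeps but can freeze the solution short of optimality.
    """

    lambda1: float = 1.0
    lambda0: float | None = None
    lambda0_form: str = "sqrt"
    tol: float = 1e-7
    max_iter: int = 500
    mu0: float | None = None
    rho: float = 1.1

    def __post_init__(self) -> None:
        if self.lambda1 <= 0:
            raise ValidationError("lambda1 must be positive")
        if self.lambda0 is not None and self.lambda0 <= 0:
            raise ValidationError("lambda0 must be positive")
        if self.lambda0_form not in ("sqrt", "linear"):
            raise ValidationError("lambda0_form must be 'sqrt' or 'linear'")
        if not 0 < self.tol < 1:
            raise ValidationError("tol must lie in (0, 1)")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")
        if self.rho <= 1:
            raise ValidationError("rho must be > 1")

    def effective_lambda0(self, shape: tuple[int, int]) -> float:
        if self.lambda0 is not None:
            return self.lambda0
        d = max(shape)
        return self.lambda1 / np.sqrt(d) if self.lambda0_form == "sqrt" else self.lambda1 / d


@dataclass
class RPCADecomposition:
    """Result of the low-rank + sparse split ``U ~= L + S``."""

    L: np.ndarray
    S: np.ndarray
    lambda0: float
    iterations: int
    converged: bool
    residual: float
    rank_L: int
    nnz_S: int

    def objective(self) -> float:
        """Convex objective ``||L||_* + lambda0 ||S||_1`` at this point."""
        return float(
            np.linalg.svd(self.L, compute_uv=False).sum()
            + self.lambda0 * np.abs(self.S).sum()
        )


def rpca_decompose(U: np.ndarray, params: RPCAParams | None = None) -> RPCADecomposition:
    """Decompose ``U`` into low-rank ``L`` plus sparse ``S`` by inexact ALM.

    Iterates soft shrinkage (prox of the l1 term) and singular-value
    thresholding (prox of the nuclear term) with a growing penalty and dual
    updates until the feasibility residual ``||U-L-S||_F / ||U||_F`` drops
    below ``params.tol``.  Returns with ``converged=False`` (no exception)
    if ``max_iter`` is exhausted.

    Raises
    ------
    DataError
        Non-finite entries in ``U``.
    """
    params = params or RPCAParams()
    U = np.asarray(U, dtype=float)
    if U.ndim != 2 or min(U.shape) < 1:
        raise ValidationError(f"U must be a 2D matrix, got shape {U.shape}")
    if not np.isfinite(U).all():
        raise DataError("non-finite entries in input matrix")

    lam0 = params.effective_lambda0(U.shape)
    norm_fro = np.linalg.norm(U)
    if norm_fro == 0:
        return RPCADecomposition(
            L=np.zeros_like(U), S=np.zeros_like(U), lambda0=lam0,
            iterations=1, converged=True, residual=0.0, rank_L=0, nnz_S=0,
        )

    norm_two = np.linalg.norm(U, 2)
    norm_inf = np.abs(U).max()
    # dual ascent starting point of the inexact-ALM scheme
    Y = U / max(norm_two, norm_inf / lam0)
    mu = params.mu0 if params.mu0 is not None else 1.25 / norm_two
    mu_max = mu * 1e7

    L = np.zeros_like(U)
    S = np.zeros_like(U)
    converged = False
    residual = 1.0
    rank = 0
    it = 0
    for it in range(1, params.max_iter + 1):
        S = soft_shrink(U - L + Y / mu, lam0 / mu)
        L, rank = singular_value_threshold(U - S + Y / mu, 1.0 / mu, return_rank=True)
        Z = U - L - S
        Y = Y + mu * Z
        mu = min(mu * params.rho, mu_max)
        residual = float(np.linalg.norm(Z) / norm_fro)
        if residual < params.tol:
            converged = True
            break

    return RPCADecomposition(
        L=L,
        S=S,
        lambda0=lam0,
        iterations=it,
        converged=converged,
        residual=residual,
        rank_L=rank,
        nnz_S=int(np.count_nonzero(S)),
    )
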