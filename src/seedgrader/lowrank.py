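"""Low-rank + sparse decomposition of joint descriptors (robust PCA).

Concatenating two 800-word histograms yields a long, redundant image
representation.  Stacking the training descriptors as the columns of a
matrix Y, the redundancy is removed by solving the convex program

    min_{X,E}  ||X||_* + lambda * ||E||_1   subject to  Y = X + E,

i.e. robust principal component analysis: X captures the correlated
(low-rank) structure shared across images and E absorbs sparse outlier
entries.  The solver is the standard inexact augmented-Lagrangian method
(alternating singular-value thresholding for X and elementwise soft
thresholding for E, with a dual update and geometric penalty growth).

Two consumption modes exist downstream.  The pipeline's default follows
the program literally: the full descriptor matrix (all images) is
decomposed jointly and the classifier works on the denoised low-rank
coordinates.  For grading images unseen at decomposition time, an
orthonormal basis spanning the dominant left singular directions of X
(smallest rank capturing 99% of the squared singular values) is extracted
and new descriptors are projected onto it; the pipeline can also run
fully in this inductive mode.

Default regularization here is lambda = 1 / sqrt(max(d, n)), the standard
robust-PCA scaling for gross sparse corruptions; the pipeline passes a
larger multiple for visual-word histograms (see its configuration).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DecompositionResult",
    "LowRankModel",
    "soft_threshold",
    "singular_value_threshold",
    "rpca_decompose",
    "fit_lowrank_basis",
    "project_descriptors",
]


@dataclass
class DecompositionResult:
    """Solution (X, E) of the low-rank + sparse program on a matrix Y."""

    X: np.ndarray
    E: np.ndarray
    lam: float
    iterations: int
    residual: float  # ||Y - X - E||_F / ||Y||_F
    converged: bool


@dataclass
class LowRankModel:
    """Orthonormal basis of the dominant left singular subspace of X."""

    basis: np.ndarray  # (d, r), basis.T @ basis = I_r
    rank: int
    singular_values: np.ndarray
    energy: float


def soft_threshold(M: np.ndarray, tau: float) -> np.ndarray:
    """Elementwise shrinkage sign(m) * max(|m| - tau, 0) (prox of the L1 norm)."""
    if tau < 0:
        raise ValueError("threshold tau must be non-negative")
    M = np.asarray(M, dtype=float)
    return np.sign(M) * np.maximum(np.abs(M) - tau, 0.0)


def singular_value_threshold(M: np.ndarray, tau: float) -> np.ndarray:
    """Shrink the singular values of M by tau (prox of the nuclear norm)."""
    if tau < 0:
        raise ValueError("threshold tau must be non-negative")
    M = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError("matrix has non-finite entries")
    u, s, vt = np.linalg.svd(M, full_matrices=False)
    s = np.maximum(s - tau, 0.0)
    keep = s > 0
    return (u[:, keep] * s[keep]) @ vt[keep]


def rpca_decompose(
    Y: np.ndarray,
    lam: float | None = None,
    tol: float = 1e-7,
    max_iter: int = 500,
    rho: float = 1.5,
) -> DecompositionResult:
    """Split Y into low-rank X plus sparse E by inexact ALM.

    Iterates X <- SVT(Y - E + L/mu, 1/mu), E <- shrink(Y - X + L/mu,
    lam/mu), L <- L + mu (Y - X - E), mu <- rho * mu, starting from
    mu = 1.25 / ||Y||_2, until the relative Frobenius residual
    ||Y - X - E||_F / ||Y||_F falls below ``tol``.

    On non-convergence within ``max_iter`` the best iterate is returned
    with ``converged=False`` and a warning.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.size == 0:
        raise ValueError("Y must be a non-empty 2-D matrix")
    if not np.all(np.isfinite(Y)):
        raise ValueError("Y has non-finite entries")
    d, n = Y.shape
    if lam is None:
        lam = 1.0 / np.sqrt(max(d, n))
    if lam <= 0:
        raise ValueError("lambda must be positive")
    norm_y = np.linalg.norm(Y)
    if norm_y == 0:
        return DecompositionResult(
            X=np.zeros_like(Y),
            E=np.zeros_like(Y),
            lam=lam,
            iterations=1,
            residual=0.0,
            converged=True,
        )
    mu = 1.25 / np.linalg.norm(Y, 2)
    dual = np.zeros_like(Y)
    E = np.zeros_like(Y)
    X = np.zeros_like(Y)
    residual = np.inf
    for it in range(1, max_iter + 1):
        X = singular_value_threshold(Y - E + dual / mu, 1.0 / mu)
        E = soft_threshold(Y - X + dual / mu, lam / mu)
        R = Y - X - E
        dual += mu * R
        mu *= rho
        residual = np.linalg.norm(R) / norm_y
        if residual <= tol:
            return DecompositionResult(X, E, lam, it, residual, True)
    warnings.warn(
        f"low-rank decomposition did not reach tol={tol:g} in "
        f"{max_iter} iterations (residual {residual:.3g})",
        stacklevel=2,
    )
    return DecompositionResult(X, E, lam, max_iter, residual, False)


def nuclear_l1_objective(X: np.ndarray, E: np.ndarray, lam: float) -> float:
    """||X||_* + lam * ||E||_1, the objective the decomposition minimizes."""
    return float(
        np.linalg.svd(X, compute_uv=False).sum() + lam * np.abs(E).sum()
    )


def fit_lowrank_basis(X: np.ndarray, energy: float = 0.99) -> LowRankModel:
    """Orthonormal basis of the smallest rank keeping ``energy`` of X.

    The rank r is the smallest number of leading singular values whose
    squared sum reaches ``energy`` of the total; ``energy=1.0`` keeps the
    full numerical rank.

    Raises
    ------
    ValueError
        For an all-zero matrix (no basis to extract).
    """
    X = np.asarray(X, dtype=float)
    if not 0 < energy <= 1:
        raise ValueError("energy must lie in (0, 1]")
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    if s.size == 0 or s[0] <= 0:
        raise ValueError("cannot fit a basis to an all-zero matrix")
    if energy >= 1.0:
        r = int(np.sum(s > s[0] * max(X.shape) * np.finfo(float).eps))
    else:
        frac = np.cumsum(s**2) / np.sum(s**2)
        r = int(np.searchsorted(frac, energy) + 1)
    r = max(r, 1)
    return LowRankModel(
        basis=u[:, :r].copy(), rank=r, singular_values=s, energy=energy
    )


def project_descriptors(model: LowRankModel, D: np.ndarray) -> np.ndarray:
    """Project (d, m) descriptor columns onto the r-dim low-rank basis."""
    D = np.asarray(D, dtype=float)
    if D.shape[0] != model.basis.shape[0]:
        raise ValueError(
            f"descriptor dimension {D.shape[0]} does not match basis "
            f"dimension {model.basis.shape[0]}"
        )
    return model.basis.T @ D
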