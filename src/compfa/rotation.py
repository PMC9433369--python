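"""Orthogonal rotations of loading matrices.

Two tools: orthogonal Procrustes alignment (used to remove rotational
indeterminacy before comparing an estimated loading matrix to its
generating value — reflections and column permutations are orthogonal,
so no separate matching step is needed) and varimax rotation for
interpretation (Kaiser's pairwise-planar-rotation algorithm with row
normalisation on by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RotationResult", "procrustes_align", "varimax", "varimax_criterion"]


@dataclass
class RotationResult:
    rotated: np.ndarray    # input @ transform
    transform: np.ndarray  # m x m orthogonal
    criterion: float       # Procrustes residual or varimax criterion


def procrustes_align(loadings, target) -> RotationResult:
    """Orthogonal T minimising ||loadings T - target||_F^2 (T = U V' from
    the SVD of loadings'target; reflections allowed)."""
    loadings = np.asarray(loadings, dtype=float)
    target = np.asarray(target, dtype=float)
    if loadings.shape != target.shape:
        raise ValueError(f"shape mismatch {loadings.shape} vs {target.shape}")
    U, _, Vt = np.linalg.svd(loadings.T @ target)
    T = U @ Vt
    rotated = loadings @ T
    return RotationResult(rotated=rotated, transform=T,
                          criterion=float(np.sum((rotated - target) ** 2)))


def varimax_criterion(loadings) -> float:
    """Sum over factors of the variance of the squared loadings."""
    L2 = np.asarray(loadings, dtype=float) ** 2
    return float(np.sum(L2.var(axis=0)))


def varimax(loadings, kaiser: bool = True, tol: float = 1e-10,
            max_iter: int = 1000) -> RotationResult:
    """Varimax rotation by iterated pairwise planar rotations.

    Kaiser row normalisation is applied during the optimisation and
    undone afterwards (``kaiser=False`` switches it off).  Columns of the
    result are sign-fixed (largest-|loading| entry positive) and ordered
    by decreasing sum of squared loadings; the returned ``transform``
    includes those column operations, so ``rotated = loadings @ transform``
    exactly.  ``criterion`` is the varimax criterion of the returned
    loadings on the scale the optimiser used (normalised if kaiser).
    For a single factor the transform is the identity (up to sign/order
    conventions, which are no-ops at m = 1).
    """
    A = np.asarray(loadings, dtype=float)
    p, m = A.shape
    if m == 1:
        return RotationResult(rotated=A.copy(), transform=np.eye(1),
                              criterion=varimax_criterion(A))
    h = np.sqrt(np.sum(A**2, axis=1))
    scale = np.where(h > 1e-12, h, 1.0) if kaiser else np.ones(p)
    L = A / scale[:, None]
    T = np.eye(m)
    crit_prev = varimax_criterion(L)
    for _ in range(max_iter):
        for i in range(m - 1):
            for j in range(i + 1, m):
                x, y = L[:, i], L[:, j]
                u = x**2 - y**2
                v = 2.0 * x * y
                num = 2.0 * (np.sum(u * v) - np.sum(u) * np.sum(v) / p)
                den = np.sum(u**2 - v**2) - (np.sum(u) ** 2 - np.sum(v) ** 2) / p
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-14:
                    continue
                c, s = np.cos(phi), np.sin(phi)
                G = np.eye(m)
                G[i, i] = G[j, j] = c
                G[i, j], G[j, i] = -s, s
                L = L @ G
                T = T @ G
        crit = varimax_criterion(L)
        if crit - crit_prev < tol:
            break
        crit_prev = crit
    # undo normalisation, fix signs, order columns by explained variance
    R = A @ T
    signs = np.where(R[np.argmax(np.abs(R), axis=0), np.arange(m)] < 0, -1.0, 1.0)
    R = R * signs
    order = np.argsort(-np.sum(R**2, axis=0), kind="stable")
    P = np.zeros((m, m))
    P[order, np.arange(m)] = 1.0
    T = (T * signs) @ P
    rotated = A @ T
    crit_scale = np.where(h > 1e-12, h, 1.0) if kaiser else np.ones(p)
    return RotationResult(rotated=rotated, transform=T,
                          criterion=varimax_criterion(rotated / crit_scale[:, None]))
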