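"""Completely-decomposed factor analysis (CDFA) with its minimum-rank
factor-analysis (MRFA) inner step.

CDFA strengthens MDFA's constraint set with S'(X - S Theta) = 0, which
makes the common factors, specific factors and errors mutually
orthogonal (S'E = 0 and F'E = 0 both hold at the solution).  The
solution is obtained in three sequential steps, all of which need only
C_XX = n^-1 X'X:

1. Theta^2 by MRFA: minimise the sum of the p - m smallest eigenvalues
   of the reduced matrix C_XX - Theta^2 subject to the reduced matrix
   staying PSD and Theta^2 >= 0.
2. Lambda = W_m Omega_m from the eigendecomposition
   C_XX - Theta^2 = W Omega^2 W' (m leading eigenvectors scaled by the
   square roots of their eigenvalues).
3. (optional) score reconstruction F, S, E in an explicit row space,
   used to verify the complete-decomposition identities.

MRFA is a concave minimisation over a spectrahedron, so the solver runs
a seeded multistart of SLSQP on the eigenvalue-sum objective with the
explicit smallest-eigenvalue constraint; SQP steps can travel along the
PSD boundary, which is where the minimisers sit.  Each candidate is
projected back to exact feasibility before scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .model_core import FASolution, FitOptions, SampleCov, psd_sqrt, sorted_eigh

__all__ = ["MrfaResult", "fit_mrfa", "fit_cdfa", "reconstruct_scores", "mrfa_objective"]

_FEAS_TOL = 1e-12


@dataclass
class MrfaResult:
    theta2: np.ndarray        # p nonnegative specific variances
    reduced_eigs: np.ndarray  # eigenvalues of C - diag(theta2), decreasing
    objective: float          # sum of the p - m smallest reduced eigenvalues
    converged: bool


def mrfa_objective(C: np.ndarray, theta2: np.ndarray, m: int) -> float:
    """Sum of the p - m smallest eigenvalues of C - diag(theta2)."""
    w = np.linalg.eigvalsh(C - np.diag(theta2))
    return float(w[: C.shape[0] - m].sum())


def _project_feasible(C: np.ndarray, theta2: np.ndarray) -> np.ndarray:
    """Clip at zero, then shrink toward 0 until C - diag(theta2) is PSD."""
    theta2 = np.maximum(theta2, 0.0)
    if np.linalg.eigvalsh(C - np.diag(theta2))[0] >= -_FEAS_TOL:
        return theta2
    lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if np.linalg.eigvalsh(C - np.diag(mid * theta2))[0] >= -_FEAS_TOL:
            lo = mid
        else:
            hi = mid
    return lo * theta2


def _slsqp_start(C: np.ndarray, m: int, x0: np.ndarray, max_iter: int):
    p = C.shape[0]

    def fg(x):
        w, W = np.linalg.eigh(C - np.diag(x))
        return w[: p - m].sum(), -(W[:, : p - m] ** 2).sum(axis=1)

    def con(x):
        return np.linalg.eigvalsh(C - np.diag(x))[0]

    def con_jac(x):
        _, W = np.linalg.eigh(C - np.diag(x))
        return -(W[:, 0] ** 2)

    res = minimize(fg, x0, jac=True, method="SLSQP",
                   bounds=[(0.0, None)] * p,
                   constraints=[{"type": "ineq", "fun": con, "jac": con_jac}],
                   options={"maxiter": max_iter, "ftol": 1e-12})
    th = _project_feasible(C, res.x)
    return th, mrfa_objective(C, th, m)


def fit_mrfa(cov: SampleCov, m: int, opts: FitOptions | None = None) -> MrfaResult:
    """Minimum-rank factor analysis for the specific variances Theta^2."""
    opts = opts or FitOptions()
    if not 1 <= m < cov.p:
        raise ValueError(f"factor count m={m} must satisfy 1 <= m < p={cov.p}")
    C = cov.C
    p = cov.p
    d = np.diag(C).copy()
    rng = np.random.default_rng(opts.seed)
    n_starts = max(opts.n_starts, 6)
    starts = [np.zeros(p), 0.5 * d, 0.9 * d]
    while len(starts) < n_starts:
        starts.append(rng.uniform(0.0, 1.0, p) * d)
    best_th, best_obj = None, np.inf
    for x0 in starts[:n_starts]:
        th, obj = _slsqp_start(C, m, x0, min(opts.max_iter, 500))
        if obj < best_obj:
            best_th, best_obj = th, obj
    w, _ = sorted_eigh(C - np.diag(best_th))
    # SLSQP has no loss trace; converged means the feasible optimum is a
    # stationary point (objective reproduced by a restart from itself)
    th2, obj2 = _slsqp_start(C, m, best_th, min(opts.max_iter, 500))
    converged = bool(obj2 >= best_obj - 1e-9)
    if obj2 < best_obj:
        best_th, best_obj = th2, obj2
        w, _ = sorted_eigh(C - np.diag(best_th))
    return MrfaResult(theta2=best_th, reduced_eigs=w,
                      objective=max(best_obj, 0.0) if abs(best_obj) < 1e-12 else best_obj,
                      converged=converged)


def fit_cdfa(cov: SampleCov, m: int, opts: FitOptions | None = None) -> FASolution:
    """Completely-decomposed FA: MRFA Theta^2 then the eigen step for Lambda."""
    opts = opts or FitOptions()
    mr = fit_mrfa(cov, m, opts)
    C = cov.C
    w, W = sorted_eigh(C - np.diag(mr.theta2))
    if np.sum(w[:m] > 1e-12) < m:
        raise np.linalg.LinAlgError(
            f"reduced matrix has fewer than m={m} positive eigenvalues")
    lam = W[:, :m] * np.sqrt(np.maximum(w[:m], 0.0))
    error_cov = C - lam @ lam.T - np.diag(mr.theta2)
    error_cov = (error_cov + error_cov.T) / 2.0
    loss = max(float(np.trace(error_cov)), 0.0)  # n^-1 ||E||^2; exact fits can round to -1e-12
    return FASolution(
        method="CDFA", loadings=lam, diag_var=mr.theta2, error_cov=error_cov,
        loss=loss, iters=1, converged=mr.converged, proper=True,
    )


def reconstruct_scores(cov: SampleCov, sol: FASolution, rows: int | None = None):
    """Explicit (F, S, E) matrices realising a CDFA solution.

    The scores are not unique; this builds one realisation in a
    ``rows``-dimensional row space from the zero-padded symmetric
    surrogate root X* (X*'X* = n C_XX):

    * S = X* C^-1 Theta + N K with N an orthonormal basis of part of the
      complement of col(X*) and K'K = n (I - Theta C^-1 Theta), so that
      S'S = n I and X*'S = n Theta;
    * F = sqrt(n) U V' from the thin SVD of (X* - S Theta) Lambda;
    * E = X* - F Lambda' - S Theta.

    Because E must be orthogonal to both F and S, the row space needs
    rows >= m + 2p (m + p dimensions for the scores plus up to p for the
    error part); the m + p rows that suffice for error-free data are not
    enough in general.
    """
    if sol.method != "CDFA":
        raise ValueError("score reconstruction is defined for CDFA solutions")
    p, m, n = sol.p, sol.m, cov.n
    rows = rows if rows is not None else m + 2 * p
    if rows < m + 2 * p:
        raise ValueError(f"rows={rows} too small: need at least m + 2p = {m + 2 * p}")
    C = cov.C
    theta = np.sqrt(np.maximum(sol.diag_var, 0.0))
    X = np.zeros((rows, p))
    X[:p] = psd_sqrt(C)
    X *= np.sqrt(n)
    B = np.linalg.solve(C, np.diag(theta))
    K = psd_sqrt(n * (np.eye(p) - np.diag(theta) @ np.linalg.solve(C, np.diag(theta))))
    N = np.zeros((rows, p))
    N[p:2 * p] = np.eye(p)
    S = X @ B + N @ K
    M = X - S * theta[None, :]
    U, _, Vt = np.linalg.svd(M @ sol.loadings, full_matrices=False)
    F = np.sqrt(n) * (U @ Vt)
    E = M - F @ sol.loadings.T
    return F, S, E
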