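"""Matrix-decomposition factor analysis (MDFA).

MDFA treats the factor scores as fixed parameters and minimises the raw
least-squares loss

    f(F, Lambda, S, Theta) = n^-1 ||X - F Lambda' - S Theta||^2

subject to the orthonormality constraints n^-1 [F, S]'[F, S] = I_{m+p}.
The solution depends on the data only through C_XX = n^-1 X'X, so the
fitter operates on a surrogate root X* (any matrix with X*'X* = n C_XX,
here sqrt(n) times the symmetric PSD square root, zero-padded to m+p
rows) and alternates

* score step — Z = [F, S] from the orthogonal-Procrustes solution
  Z = sqrt(n) U V' of the thin SVD X* A = U D V' with A = [Lambda, Theta];
* parameter step — Lambda = n^-1 X*'F and theta_j = n^-1 (S'X*)_jj, the
  exact conditional minimisers.

Both steps are conditionally optimal, so the loss sequence is
non-increasing.  The converged solution satisfies F'E = 0 and
diag(S'E) = 0 but, unlike CDFA, not the full S'E = 0: the off-diagonal
error/specific-factor couplings remain, which is why the MDFA Theta^2
absorbs the diagonal of the realised error scatter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import FASolution, FitOptions, SampleCov, psd_sqrt, sorted_eigh

__all__ = ["MdfaState", "fit_mdfa", "mdfa_diagnostics", "surrogate_root"]


@dataclass
class MdfaState:
    """Converged internals of an MDFA run (scores are not unique; only
    Lambda, Theta^2 and C_EE are interpreted)."""

    surrogate_root: np.ndarray  # r x p, X*'X* = n C_XX
    scores: np.ndarray          # r x (m+p), [F, S], n^-1 Z'Z = I
    loadings: np.ndarray        # p x m
    theta: np.ndarray           # p vector, diagonal of Theta (sign-free)
    loss: float
    n: int

    @property
    def m(self) -> int:
        return self.loadings.shape[1]

    @property
    def F(self) -> np.ndarray:
        return self.scores[:, : self.m]

    @property
    def S(self) -> np.ndarray:
        return self.scores[:, self.m:]

    @property
    def E(self) -> np.ndarray:
        return (self.surrogate_root - self.F @ self.loadings.T
                - self.S * self.theta[None, :])


def surrogate_root(cov: SampleCov, rows: int | None = None, kind: str = "sym") -> np.ndarray:
    """A rows x p matrix X* with X*'X* = n C_XX (rows >= p).

    ``kind`` selects the p x p root: "sym" (symmetric PSD square root) or
    "chol" (upper-triangular Cholesky factor); remaining rows are zero.
    The fitted loss and parameters are root-independent.
    """
    p = cov.p
    rows = rows if rows is not None else p + 1
    if rows < p:
        raise ValueError("surrogate root needs at least p rows")
    if kind == "sym":
        R = psd_sqrt(cov.C)
    elif kind == "chol":
        R = np.linalg.cholesky(cov.C).T
    else:
        raise ValueError(f"unknown root kind {kind!r}")
    X = np.zeros((rows, p))
    X[:p] = R
    return np.sqrt(cov.n) * X


def _init_params(C: np.ndarray, m: int, rng=None):
    w, W = sorted_eigh(C)
    lam = W[:, :m] * np.sqrt(np.maximum(w[:m], 0.0))
    if rng is not None:
        lam = lam + rng.normal(scale=0.1, size=lam.shape)
    theta = np.sqrt(np.maximum(np.diag(C) - np.sum(lam**2, axis=1), 0.01))
    return lam, theta


def fit_mdfa(cov: SampleCov, m: int, opts: FitOptions | None = None,
             root: str = "sym", return_state: bool = False):
    """Fit MDFA; returns an FASolution (and the MdfaState if requested)."""
    opts = opts or FitOptions()
    if not 1 <= m < cov.p:
        raise ValueError(f"factor count m={m} must satisfy 1 <= m < p={cov.p}")
    C = cov.C
    n = cov.n
    p = cov.p
    X = surrogate_root(cov, rows=p + m, kind=root)
    rng = np.random.default_rng(opts.seed)
    best = None
    for start in range(opts.n_starts):
        lam, theta = _init_params(C, m, rng if start else None)
        trace = []
        loss_prev = np.inf
        converged = False
        for it in range(1, opts.max_iter + 1):
            A = np.hstack([lam, np.diag(theta)])       # p x (m+p)
            U, _, Vt = np.linalg.svd(X @ A, full_matrices=False)
            Z = np.sqrt(n) * (U @ Vt)
            F, S = Z[:, :m], Z[:, m:]
            lam = X.T @ F / n
            theta = np.einsum("ij,ij->j", S, X) / n
            E = X - F @ lam.T - S * theta[None, :]
            loss = float(np.sum(E**2)) / n
            trace.append(loss)
            if abs(loss_prev - loss) < opts.tol * max(1.0, loss):
                converged = True
                break
            loss_prev = loss
        state = MdfaState(surrogate_root=X, scores=Z, loadings=lam,
                          theta=theta, loss=trace[-1], n=n)
        if best is None or state.loss < best[0].loss - 1e-15:
            error_cov = E.T @ E / n
            error_cov = (error_cov + error_cov.T) / 2.0
            sol = FASolution(
                method="MDFA", loadings=lam, diag_var=theta**2,
                error_cov=error_cov, loss=trace[-1], iters=len(trace),
                converged=converged, proper=True, loss_trace=np.asarray(trace),
            )
            best = (sol, state)
    return best if return_state else best[0]


def mdfa_diagnostics(state: MdfaState) -> dict:
    """Constraint residuals of a converged MDFA solution.

    At the optimum F'E = 0 and diag(S'E) = 0 hold, while the
    off-diagonal part of S'E is generally nonzero — the defining gap
    between MDFA and CDFA.
    """
    F, S, E = state.F, state.S, state.E
    FE = F.T @ E / state.n
    SE = S.T @ E / state.n
    off = SE - np.diag(np.diag(SE))
    return {
        "max_abs_FE": float(np.max(np.abs(FE))),
        "max_abs_diag_SE": float(np.max(np.abs(np.diag(SE)))),
        "max_abs_offdiag_SE": float(np.max(np.abs(off))),
    }
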