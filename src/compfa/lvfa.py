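"""Latent-variable factor analysis (LVFA) by least squares and maximum
likelihood.

LVFA models the covariance as C[x, x] = Lambda Lambda' + Psi^2 with
diagonal Psi^2 of unique variances; the specific-factor and error parts
of the comprehensive model are left unseparated in Psi u.  Two fitters
are provided:

* least squares — minimise ||C_XX - (Lambda Lambda' + Psi^2)||_F^2 by a
  principal-factor alternation: the best PSD rank-m approximation of the
  reduced matrix C_XX - Psi^2 updates Lambda, and the stationarity
  identity Psi^2 = diag(C_XX - Lambda Lambda') updates Psi^2.  The
  unique variances are deliberately unconstrained in sign so Heywood
  (improper) solutions are detectable via ``proper=False``.

* maximum likelihood — minimise the normal-theory discrepancy
  tr(C_XX Sigma^-1) - log|C_XX Sigma^-1| - p over Sigma = Lambda Lambda'
  + Psi^2, by EM (monotone) followed by a quasi-Newton refinement of the
  profile discrepancy in log Psi^2, which drives the loss to machine
  precision when an exact fit exists.  Psi^2 is floored at
  ``FitOptions.variance_floor``.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from .model_core import FASolution, FitOptions, SampleCov, sorted_eigh

__all__ = ["fit_lvfa_ls", "fit_lvfa_ml", "ml_discrepancy"]


def _check_m(cov: SampleCov, m: int) -> None:
    if not 1 <= m < cov.p:
        raise ValueError(f"factor count m={m} must satisfy 1 <= m < p={cov.p}")


def _psi2_starts(C: np.ndarray, opts: FitOptions):
    d = np.diag(C).copy()
    rng = np.random.default_rng(opts.seed)
    yield 0.5 * d
    for _ in range(opts.n_starts - 1):
        yield rng.uniform(0.2, 0.8, size=d.shape) * d


def _leading_loadings(reduced: np.ndarray, m: int) -> np.ndarray:
    """Best PSD rank-m factor of a symmetric matrix: m leading eigenpairs,
    negative retained eigenvalues truncated to zero."""
    w, W = sorted_eigh(reduced)
    lam = W[:, :m] * np.sqrt(np.maximum(w[:m], 0.0))
    return lam


def fit_lvfa_ls(cov: SampleCov, m: int, opts: FitOptions | None = None) -> FASolution:
    """Least-squares LVFA; returns the best local minimum over starts."""
    opts = opts or FitOptions()
    _check_m(cov, m)
    C = cov.C
    best = None
    for psi2 in _psi2_starts(C, opts):
        psi2 = psi2.copy()
        trace = []
        loss_prev = np.inf
        converged = False
        lam = np.zeros((cov.p, m))
        for it in range(1, opts.max_iter + 1):
            lam = _leading_loadings(C - np.diag(psi2), m)
            psi2 = np.diag(C - lam @ lam.T).copy()
            loss = float(np.sum((C - lam @ lam.T - np.diag(psi2)) ** 2))
            trace.append(loss)
            if abs(loss_prev - loss) < opts.tol * max(1.0, loss):
                converged = True
                break
            loss_prev = loss
        sol = FASolution(
            method="LVFA-LS", loadings=lam, diag_var=psi2, error_cov=None,
            loss=trace[-1], iters=len(trace), converged=converged,
            proper=bool(psi2.min() >= 0.0), loss_trace=np.asarray(trace),
        )
        if best is None or sol.loss < best.loss:
            best = sol
    return best


def ml_discrepancy(C: np.ndarray, sigma: np.ndarray) -> float:
    """Normal-theory discrepancy tr(C Sigma^-1) - log|C Sigma^-1| - p."""
    p = C.shape[0]
    L = np.linalg.cholesky(sigma)
    A = np.linalg.solve(L, C)
    A = np.linalg.solve(L, A.T).T  # Sigma^-1 applied to C (via two triangular solves)
    sign_c, logdet_c = np.linalg.slogdet(C)
    if sign_c <= 0:
        raise np.linalg.LinAlgError("C_XX is singular; ML estimation needs a positive definite input")
    logdet_sigma = 2.0 * np.sum(np.log(np.diag(L)))
    return float(np.trace(A) - (logdet_c - logdet_sigma) - p)


def _profile_ml(C: np.ndarray, psi2: np.ndarray, m: int):
    """Profile Lambda out of the ML discrepancy for fixed Psi^2.

    With C~ = Psi^-1 C Psi^-1 = W Gamma W', the conditionally optimal
    loadings are Lambda = Psi W_m (Gamma_m - I)^{1/2}_+ and the profile
    discrepancy is the sum of gamma_k - log gamma_k - 1 over the
    eigenvalues not absorbed by the factors.
    """
    psi = np.sqrt(psi2)
    Ct = C / np.outer(psi, psi)
    g, W = sorted_eigh(Ct)
    g = np.maximum(g, 1e-300)
    lam = (W[:, :m] * np.sqrt(np.maximum(g[:m] - 1.0, 0.0))) * psi[:, None]
    terms = g - np.log(g) - 1.0
    val = float(np.sum(terms[m:]) + np.sum(terms[:m][g[:m] < 1.0]))
    return val, lam


def fit_lvfa_ml(cov: SampleCov, m: int, opts: FitOptions | None = None) -> FASolution:
    """Maximum-likelihood LVFA (EM with quasi-Newton profile refinement)."""
    opts = opts or FitOptions()
    _check_m(cov, m)
    C = cov.C
    p = cov.p
    if np.linalg.eigvalsh(C)[0] <= 0:
        raise np.linalg.LinAlgError("C_XX is singular; ML estimation needs a positive definite input")
    floor = max(opts.variance_floor, 1e-12)
    best = None
    for psi2 in _psi2_starts(C, opts):
        psi2 = np.maximum(psi2, floor)
        lam = _leading_loadings(C - np.diag(psi2), m)
        trace = []
        converged = False
        loss_prev = np.inf
        for it in range(1, opts.max_iter + 1):
            sigma = lam @ lam.T + np.diag(psi2)
            loss = ml_discrepancy(C, sigma)
            trace.append(loss)
            if abs(loss_prev - loss) < opts.tol * max(1.0, abs(loss)):
                converged = True
                break
            loss_prev = loss
            # EM update for the normal factor model given C_XX
            beta = np.linalg.solve(sigma, lam).T          # m x p, Lambda' Sigma^-1
            M = np.eye(m) - beta @ lam + beta @ C @ beta.T
            lam = C @ beta.T @ np.linalg.inv(M)
            psi2 = np.maximum(np.diag(C - lam @ beta @ C).copy(), floor)

        # quasi-Newton refinement on the profile discrepancy; bounded
        # linear scale lets Heywood coordinates land exactly on the floor
        def fun(x):
            val, _ = _profile_ml(C, x, m)
            return val

        res = minimize(fun, psi2, method="L-BFGS-B",
                       bounds=[(floor, None)] * p,
                       options={"maxiter": 1000, "ftol": 1e-16, "gtol": 1e-12})
        val, lam_r = _profile_ml(C, np.maximum(res.x, floor), m)
        if val < trace[-1]:
            psi2 = np.maximum(res.x, floor)
            lam = lam_r
            trace.append(val)
        loss = trace[-1]
        sol = FASolution(
            method="LVFA-ML", loadings=lam, diag_var=psi2, error_cov=None,
            loss=loss, iters=len(trace), converged=converged,
            proper=bool(psi2.min() >= 0.0), loss_trace=np.asarray(trace),
        )
        if best is None or sol.loss < best.loss:
            best = sol
    return best
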