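"""Shared model objects and covariance-structure primitives.

The comprehensive factor-analysis (CompFA) model splits a centred
p-variate observation into a common-factor part, a specific-factor part
and an error part,

    x = Lambda f + Theta s + e,

with ``Lambda`` (p x m) the loading matrix, ``Theta`` (p x p, diagonal)
the specific-factor coefficients and ``e`` an error vector.  Every
estimator in this package consumes only the p x p product-moment matrix
C_XX = n^-1 X'X, for which the model implies

    C_XX = Lambda Lambda' + Theta^2 + C_EE,

where C_EE = n^-1 E'E is the realised error scatter.  This module holds
the validated covariance container, the solution container shared by all
estimators, and the handful of small linear-algebra conventions (sorted
eigendecomposition with a deterministic sign rule, PSD square root) that
keep the estimators reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SampleCov",
    "FASolution",
    "FitOptions",
    "validate_covariance",
    "implied_cov",
    "communalities",
    "sorted_eigh",
    "psd_sqrt",
    "read_covariance_csv",
    "write_loadings_csv",
    "write_variances_csv",
]

#: relative symmetry / PSD tolerance (times trace); matrices here are
#: small (p <= 24) and double precision, so a tight bound is safe.
REL_TOL = 1e-10


@dataclass(frozen=True)
class SampleCov:
    """A validated p x p covariance (or correlation) matrix with nominal n."""

    C: np.ndarray
    n: int
    p: int
    is_correlation: bool = False

    def __post_init__(self):  # defensive: keep the stored matrix immutable
        self.C.setflags(write=False)


@dataclass
class FitOptions:
    """Numerical knobs shared by all fitters.

    tol            relative-loss convergence tolerance
    max_iter       iteration cap per start
    n_starts       number of (seeded) starting points
    seed           RNG seed for start perturbations
    variance_floor lower bound on unique variances in ML estimation
    """

    tol: float = 1e-8
    max_iter: int = 5000
    n_starts: int = 1
    seed: int = 0
    variance_floor: float = 1e-6

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")


@dataclass
class FASolution:
    """Output of one factor-analysis fit.

    ``diag_var`` is Psi^2 (unique variances) for the latent-variable
    fitters and Theta^2 (specific variances) for the decomposition
    fitters; ``error_cov`` is the implied error scatter C_EE, absent
    (None) for latent-variable solutions which leave the specific and
    error parts unseparated.
    """

    method: str
    loadings: np.ndarray
    diag_var: np.ndarray
    error_cov: Optional[np.ndarray]
    loss: float
    iters: int
    converged: bool
    proper: bool
    loss_trace: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def p(self) -> int:
        return self.loadings.shape[0]

    @property
    def m(self) -> int:
        return self.loadings.shape[1]


def validate_covariance(C, n: int) -> SampleCov:
    """Validate and wrap a square covariance/correlation matrix.

    The matrix is symmetrised as (C + C')/2 before the checks; asymmetry
    or a negative eigenvalue beyond ``REL_TOL * trace`` raises, as does a
    nominal sample size n <= p (the model supposes n > p > m).
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError(f"covariance matrix must be square, got shape {C.shape}")
    p = C.shape[0]
    scale = max(abs(np.trace(C)), 1.0)
    tol = REL_TOL * scale
    if np.max(np.abs(C - C.T)) > tol:
        raise ValueError("matrix is not symmetric within tolerance")
    C = (C + C.T) / 2.0
    w = np.linalg.eigvalsh(C)
    if w[0] < -tol:
        raise ValueError(f"matrix is not positive semidefinite (min eigenvalue {w[0]:.3e})")
    n = int(n)
    if n <= p:
        raise ValueError(f"nominal sample size n={n} must exceed the dimension p={p}")
    is_corr = bool(np.allclose(np.diag(C), 1.0, atol=1e-8))
    return SampleCov(C=C, n=n, p=p, is_correlation=is_corr)


def implied_cov(loadings, diag_var, error_cov=None) -> np.ndarray:
    """Model-implied covariance Lambda Lambda' + diag(diag_var) + C_EE."""
    loadings = np.asarray(loadings, dtype=float)
    diag_var = np.asarray(diag_var, dtype=float)
    p = loadings.shape[0]
    if diag_var.shape != (p,):
        raise ValueError("diag_var must be a length-p vector")
    common = loadings @ loadings.T
    common = (common + common.T) / 2.0
    out = common + np.diag(diag_var)
    if error_cov is not None:
        error_cov = np.asarray(error_cov, dtype=float)
        if error_cov.shape != (p, p):
            raise ValueError("error_cov must be p x p")
        out = out + (error_cov + error_cov.T) / 2.0
    return out


def communalities(loadings) -> np.ndarray:
    """Row-wise squared norms ||lambda_j||^2 — variance explained by the
    common factors per variable; invariant to orthogonal rotation."""
    loadings = np.asarray(loadings, dtype=float)
    return np.sum(loadings**2, axis=1)


def sorted_eigh(M):
    """Eigendecomposition with eigenvalues in decreasing order and a
    deterministic sign rule: the largest-magnitude component of each
    eigenvector is made nonnegative (first such index on exact ties)."""
    w, W = np.linalg.eigh(M)
    order = np.argsort(w)[::-1]
    w = w[order]
    W = W[:, order]
    for k in range(W.shape[1]):
        j = int(np.argmax(np.abs(W[:, k])))
        if W[j, k] < 0:
            W[:, k] = -W[:, k]
    return w, W


def psd_sqrt(M) -> np.ndarray:
    """Symmetric PSD square root; tiny negative eigenvalues clipped at 0."""
    w, W = sorted_eigh(np.asarray(M, dtype=float))
    w = np.maximum(w, 0.0)
    R = (W * np.sqrt(w)) @ W.T
    return (R + R.T) / 2.0


# --- CSV interfaces -------------------------------------------------------

def read_covariance_csv(path, n: int) -> SampleCov:
    """Read a square numeric covariance table (optional header row of
    variable names); missing values are rejected."""
    df = pd.read_csv(path)
    # headerless all-numeric files: re-read without a header
    try:
        [float(c) for c in df.columns]
        df = pd.read_csv(path, header=None)
    except ValueError:
        pass
    if df.isna().any().any():
        raise ValueError("covariance CSV contains missing values")
    return validate_covariance(df.to_numpy(dtype=float), n)


def write_loadings_csv(path, loadings, variables=None) -> None:
    loadings = np.asarray(loadings)
    p, m = loadings.shape
    idx = variables if variables is not None else [f"v{j+1}" for j in range(p)]
    pd.DataFrame(loadings, index=idx,
                 columns=[f"factor{k+1}" for k in range(m)]).to_csv(path, index_label="variable")


def write_variances_csv(path, sol: FASolution, variables=None) -> None:
    p = sol.p
    idx = variables if variables is not None else [f"v{j+1}" for j in range(p)]
    ev = np.full(p, np.nan) if sol.error_cov is None else np.diag(sol.error_cov)
    pd.DataFrame({"diag_var": sol.diag_var, "error_variance": ev},
                 index=idx).to_csv(path, index_label="variable")
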