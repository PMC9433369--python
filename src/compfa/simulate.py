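"""Synthetic CompFA covariance generator for the Monte-Carlo design.

One replication of the study draws a truth set — loadings with entries
uniform on [-1, 1] (redrawn until numerical rank m), specific variances
uniform on [0.1, 0.8] — and builds covariance matrices under 12
conditions: model version (nonrandom N / random R) x error-correlation
level (C_N none, C_L low, C_H high) x error magnitude (E_L, E_H).

Errors are e_i = alpha * eps_i with eps_i ~ N_p(0, Phi).  At C_N the
pre-scaling error covariance Phi is the diagonal matrix D_R with entries
uniform on [0.1, 0.8]; at C_L/C_H it is D_R^{1/2} R D_R^{1/2} where the
correlation matrix R has unit diagonal and off-diagonals tau_jk r~_jk,
with r~_jk ~ N(0.2 rho, (0.05 rho)^2) truncated to (-1, 1) and rho = 1
(C_L) or 2 (C_H) and tau_jk an independent random sign.  R must be
positive semidefinite to serve as a correlation matrix: PSD draws are
kept as-is (rejection sampling), and when no PSD draw occurs — at
rho = 2 an i.i.d.-sign draw is essentially never PSD for p >= 10 — the
draw is projected to the nearest PSD matrix and rescaled to unit
diagonal, which shrinks the off-diagonals somewhat while keeping their
random structure.

The scale alpha solves tr(alpha^2 Phi) / tr(Lambda Lambda') = 0.1 (E_L)
or 0.2 (E_H), i.e. the ratio is applied to the effective error
covariance alpha^2 Phi.

N version:  C_XX = Lambda Lambda' + Theta^2 + n^-1 sum e_i e_i'  (the
structural part is exact; only the error scatter is sampled).
R version:  C_XX = n^-1 sum x_i x_i' with x_i = Lambda f_i + Theta s_i
+ e_i and [f_i; s_i] ~ N(0, I_{m+p}) (raw second moments, no
recentring).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model_core import SampleCov, psd_sqrt, validate_covariance

__all__ = [
    "TruthSet",
    "SimulationCondition",
    "SimulatedCov",
    "CORR_LEVELS",
    "ERROR_LEVELS",
    "VERSIONS",
    "draw_truth",
    "build_error_cov",
    "scale_errors",
    "gen_cov_nonrandom",
    "gen_cov_random",
    "gen_strong_condition_cov",
    "generate_condition",
]

CORR_LEVELS = ("CN", "CL", "CH")
ERROR_LEVELS = ("EL", "EH")
VERSIONS = ("N", "R")

_RHO = {"CL": 1.0, "CH": 2.0}
_ERROR_RATIO = {"EL": 0.1, "EH": 0.2}


@dataclass
class TruthSet:
    """Generating parameters for one replication/condition."""

    loadings_true: np.ndarray       # p x m, entries in [-1, 1], rank m
    theta2_true: np.ndarray         # p, entries in [0.1, 0.8]
    phi: Optional[np.ndarray] = None  # p x p pre-scaling error covariance
    alpha: float = 0.0              # error scale, e_i = alpha * eps_i
    seed: int = 0

    @property
    def p(self) -> int:
        return self.loadings_true.shape[0]

    @property
    def m(self) -> int:
        return self.loadings_true.shape[1]


@dataclass(frozen=True)
class SimulationCondition:
    version: str      # "N" or "R"
    corr_level: str   # "CN", "CL", "CH"
    error_level: str  # "EL", "EH"
    n: int = 200
    p: int = 12
    m: int = 3

    def __post_init__(self):
        if self.version not in VERSIONS:
            raise ValueError(f"unknown version {self.version!r}")
        if self.corr_level not in CORR_LEVELS:
            raise ValueError(f"unknown correlation level {self.corr_level!r}")
        if self.error_level not in ERROR_LEVELS:
            raise ValueError(f"unknown error level {self.error_level!r}")
        if not self.n > self.p > self.m:
            raise ValueError("the design requires n > p > m")


@dataclass
class SimulatedCov:
    cov: SampleCov
    truth: TruthSet
    dee_true: np.ndarray   # diag of the realised error scatter
    cee_true: np.ndarray   # realised error scatter n^-1 E'E


def draw_truth(p: int, m: int, rng: np.random.Generator):
    """Draw (loadings, specific variances); loadings redrawn until the
    smallest singular value exceeds 1e-8 (cap 100 attempts)."""
    if not p > m >= 1:
        raise ValueError("need p > m >= 1")
    for _ in range(100):
        lam = rng.uniform(-1.0, 1.0, size=(p, m))
        if np.linalg.svd(lam, compute_uv=False)[-1] > 1e-8:
            theta2 = rng.uniform(0.1, 0.8, size=p)
            return lam, theta2
    raise RuntimeError("could not draw a rank-m loading matrix in 100 attempts")


def _draw_corr(p: int, rho: float, rng: np.random.Generator, max_tries: int = 200):
    """Random error-correlation matrix with off-diagonals tau_jk * r~_jk.

    Rejection sampling keeps the drawn matrix whenever it is already PSD
    (the usual outcome at rho = 1 for moderate p).  When no PSD draw
    occurs within ``max_tries`` — at rho = 2 and p >= 10 an i.i.d.-sign
    draw is PSD with vanishing probability — the last draw is projected
    to the nearest PSD matrix (eigenvalue clipping) and rescaled to unit
    diagonal, which preserves the random sign/magnitude structure at the
    price of some shrinkage of the off-diagonals.
    """
    R = np.eye(p)
    for _ in range(max_tries):
        for j in range(p):
            for k in range(j + 1, p):
                while True:
                    r = rng.normal(0.2 * rho, 0.05 * rho)
                    if -1.0 < r < 1.0:
                        break
                tau = 1.0 if rng.uniform() < 0.5 else -1.0
                R[j, k] = R[k, j] = tau * r
        if np.linalg.eigvalsh(R)[0] >= -1e-12:
            return R
    w, W = np.linalg.eigh(R)
    R = (W * np.maximum(w, 0.0)) @ W.T
    d = np.sqrt(np.diag(R))
    R = R / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return (R + R.T) / 2.0


def build_error_cov(p: int, corr_level: str, rng: np.random.Generator,
                    d_r: Optional[np.ndarray] = None) -> np.ndarray:
    """Pre-scaling error covariance Phi for one correlation level.

    ``d_r`` lets callers share the variance profile D_R across the
    conditions of one replication; if omitted it is drawn U(0.1, 0.8).
    """
    if corr_level not in CORR_LEVELS:
        raise ValueError(f"unknown correlation level {corr_level!r}")
    if d_r is None:
        d_r = rng.uniform(0.1, 0.8, size=p)
    d_r = np.asarray(d_r, dtype=float)
    if corr_level == "CN":
        return np.diag(d_r)
    R = _draw_corr(p, _RHO[corr_level], rng)
    root = np.sqrt(d_r)
    return R * np.outer(root, root)


def scale_errors(phi: np.ndarray, loadings_true: np.ndarray, error_level: str) -> float:
    """alpha with tr(alpha^2 Phi) / tr(Lambda Lambda') equal to the
    level's target ratio (0.1 for E_L, 0.2 for E_H)."""
    tr_phi = float(np.trace(phi))
    tr_common = float(np.sum(loadings_true**2))
    if tr_common <= 0:
        raise ValueError("true loadings are all zero")
    if tr_phi <= 0:
        raise ValueError("error covariance has nonpositive trace")
    return float(np.sqrt(_ERROR_RATIO[error_level] * tr_common / tr_phi))


def _draw_errors(truth: TruthSet, n: int, rng: np.random.Generator) -> np.ndarray:
    A = psd_sqrt(truth.phi)
    return truth.alpha * (rng.standard_normal((n, truth.p)) @ A.T)


def gen_cov_nonrandom(truth: TruthSet, n: int, rng: np.random.Generator,
                      max_tries: int = 100) -> SimulatedCov:
    """Nonrandom-version covariance: exact structural part plus a sampled
    error scatter; redrawn in the (rare) rank-deficient case."""
    p = truth.p
    if n <= p:
        raise ValueError("need n > p")
    struct = truth.loadings_true @ truth.loadings_true.T
    struct = (struct + struct.T) / 2.0 + np.diag(truth.theta2_true)
    for _ in range(max_tries):
        E = _draw_errors(truth, n, rng)
        cee = E.T @ E / n
        cee = (cee + cee.T) / 2.0
        C = struct + cee
        if np.linalg.matrix_rank(C) == p:
            return SimulatedCov(cov=validate_covariance(C, n), truth=truth,
                                dee_true=np.diag(cee).copy(), cee_true=cee)
    raise RuntimeError("persistent rank deficiency in simulated covariance")


def gen_cov_random(truth: TruthSet, n: int, rng: np.random.Generator,
                   max_tries: int = 100) -> SimulatedCov:
    """Random-version covariance: raw second moments of sampled scores."""
    p, m = truth.p, truth.m
    if n <= p:
        raise ValueError("need n > p")
    theta = np.sqrt(truth.theta2_true)
    for _ in range(max_tries):
        F = rng.standard_normal((n, m))
        S = rng.standard_normal((n, p))
        E = _draw_errors(truth, n, rng)
        X = F @ truth.loadings_true.T + S * theta[None, :] + E
        C = X.T @ X / n
        C = (C + C.T) / 2.0
        cee = E.T @ E / n
        cee = (cee + cee.T) / 2.0
        if np.linalg.matrix_rank(C) == p:
            return SimulatedCov(cov=validate_covariance(C, n), truth=truth,
                                dee_true=np.diag(cee).copy(), cee_true=cee)
    raise RuntimeError("persistent rank deficiency in simulated covariance")


def gen_strong_condition_cov(truth: TruthSet, dee: np.ndarray, n: int = 200) -> SimulatedCov:
    """Covariance meeting the strong uncorrelated-error condition exactly:
    the realised error scatter is the diagonal matrix diag(dee), under
    which all estimators fit perfectly."""
    dee = np.asarray(dee, dtype=float)
    if np.any(dee < 0):
        raise ValueError("dee must be nonnegative")
    C = (truth.loadings_true @ truth.loadings_true.T
         + np.diag(truth.theta2_true + dee))
    return SimulatedCov(cov=validate_covariance(C, n), truth=truth,
                        dee_true=dee.copy(), cee_true=np.diag(dee))


def generate_condition(condition: SimulationCondition, loadings_true, theta2_true,
                       phi: np.ndarray, rng: np.random.Generator) -> SimulatedCov:
    """Build one cell's covariance from shared truth and a prepared Phi."""
    alpha = scale_errors(phi, loadings_true, condition.error_level)
    truth = TruthSet(loadings_true=loadings_true, theta2_true=theta2_true,
                     phi=phi, alpha=alpha)
    gen = gen_cov_nonrandom if condition.version == "N" else gen_cov_random
    return gen(truth, condition.n, rng)
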