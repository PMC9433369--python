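"""Parameter-recovery metrics and the per-variable variance decomposition.

The mean absolute difference (MAD) between an estimated parameter matrix
and its generating value is the L1 norm of the difference divided by the
entry count: p*m for loadings (after orthogonal Procrustes alignment to
the truth), p for diagonal variance matrices.  For latent-variable fits
the diagonal estimate is Psi^2 (unique variances); for the
decomposition fits it is Theta^2 (specific variances).  Both references
matter: the generating Theta^2 itself, and Theta^2 + D_EE with D_EE the
diagonal of the realised error scatter — the quantity the LVFA and MDFA
estimates actually track.

The Delta statistic is the LVFA MAD(Theta^2) minus the MDFA
MAD(Theta^2); a positive value means the MDFA specific variances are
closer to the generating ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .model_core import FASolution, SampleCov, communalities
from .simulate import SimulationCondition

__all__ = [
    "RecoveryRecord",
    "mad_loadings",
    "mad_diag",
    "delta_stat",
    "variance_decomposition",
]


@dataclass
class RecoveryRecord:
    mad_lambda: float
    mad_theta2: float
    mad_theta2_plus_dee: float
    method: str
    condition: Optional[SimulationCondition] = None
    replication: int = 0


def mad_loadings(estimate, truth) -> float:
    """L1 difference / (p*m); the estimate is expected to be already
    Procrustes-aligned to the truth."""
    estimate = np.asarray(estimate, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimate.shape != truth.shape:
        raise ValueError(f"shape mismatch {estimate.shape} vs {truth.shape}")
    return float(np.abs(estimate - truth).sum() / estimate.size)


def mad_diag(est_diag, ref_diag) -> float:
    """L1 difference / p between two diagonal-variance vectors."""
    est_diag = np.asarray(est_diag, dtype=float)
    ref_diag = np.asarray(ref_diag, dtype=float)
    if est_diag.shape != ref_diag.shape:
        raise ValueError(f"length mismatch {est_diag.shape} vs {ref_diag.shape}")
    return float(np.abs(est_diag - ref_diag).mean())


def delta_stat(rec_lvfa: RecoveryRecord, rec_mdfa: RecoveryRecord) -> float:
    """Delta = MAD_theta2(LVFA) - MAD_theta2(MDFA) for one paired fit."""
    if (rec_lvfa.condition != rec_mdfa.condition
            or rec_lvfa.replication != rec_mdfa.replication):
        raise ValueError("records are not a matched (condition, replication) pair")
    return float(rec_lvfa.mad_theta2 - rec_mdfa.mad_theta2)


def variance_decomposition(sol: FASolution, cov: SampleCov) -> pd.DataFrame:
    """Per-variable split of diag(C_XX) into communality, specific (or
    unique) variance, and error variance.

    For decomposition fits the three parts sum to the variable's
    variance; for latent-variable fits the error column is missing (the
    specific and error parts are unseparated) and communality plus unique
    variance reproduces the variance.
    """
    comm = communalities(sol.loadings)
    if sol.error_cov is None:
        ev = np.full(sol.p, np.nan)
    else:
        ev = np.diag(sol.error_cov).copy()
    total = comm + sol.diag_var + np.where(np.isnan(ev), 0.0, ev)
    return pd.DataFrame({
        "communality": comm,
        "specific_variance": sol.diag_var,
        "error_variance": ev,
        "total": total,
        "observed_variance": np.diag(cov.C),
    }, index=[f"v{j+1}" for j in range(sol.p)])
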