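import numpy as np
import pytest

from compfa.model_core import validate_covariance
from compfa.simulate import (SimulationCondition, TruthSet, build_error_cov,
                             draw_truth, gen_strong_condition_cov,
                             generate_condition)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def truth12(rng):
    """A p=12, m=3 truth set matching the study's truth distribution."""
    lam, theta2 = draw_truth(12, 3, rng)
    return lam, theta2


@pytest.fixture
def strong_sim(truth12, rng):
    """Strong-condition covariance: exact low-rank + diagonal structure."""
    lam, theta2 = truth12
    dee = rng.uniform(0.05, 0.3, size=12)
    return gen_strong_condition_cov(TruthSet(lam, theta2), dee)


@pytest.fixture
def errorfree_cov(truth12):
    lam, theta2 = truth12
    return validate_covariance(lam @ lam.T + np.diag(theta2), 200), lam, theta2


@pytest.fixture
def correlated_sim(truth12, rng):
    """One high-correlation, high-magnitude error cell (the regime where
    the estimators genuinely disagree)."""
    lam, theta2 = truth12
    phi = build_error_cov(12, "CH", rng)
    cond = SimulationCondition("N", "CH", "EH", 200, 12, 3)
    return generate_condition(cond, lam, theta2, phi, rng)


def random_psd(p, rng, as_corr=False):
    A = rng.normal(size=(p, p + 2))
    C = A @ A.T / (p + 2)
    if as_corr:
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
        np.fill_diagonal(C, 1.0)
    return (C + C.T) / 2.0


def random_orthogonal(m, rng):
    Q, R = np.linalg.qr(rng.normal(size=(m, m)))
    return Q * np.sign(np.diag(R))
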