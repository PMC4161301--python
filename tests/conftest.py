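"""Shared fixtures: small simulated datasets and independent oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest

from esnpquartets.synthetic import PlantedBifan, PlantedMediation, SimulationConfig, simulate


@pytest.fixture(scope="session")
def bifan_dataset():
    """One planted bi-fan (unit slopes) at n=200 plus noise SNPs/genes."""
    cfg = SimulationConfig(
        n_samples=200,
        n_snps=20,
        n_genes=20,
        maf_range=(0.3, 0.3),
        planted_bifans=[PlantedBifan()],
        master_seed=11,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def noise_dataset():
    """Pure-noise genotypes and expression at the default cohort size."""
    cfg = SimulationConfig(n_samples=50, n_snps=60, n_genes=40, master_seed=23)
    return simulate(cfg)


# ---------------------------------------------------------------------------
# Independent oracles

def fisher_two_sided_enumeration(table) -> float:
    """Two-sided Fisher's exact p by full hypergeometric enumeration.

    Sums the probabilities of every table with the observed margins
    whose hypergeometric probability does not exceed the observed
    table's (with a small relative tolerance for float ties).
    """
    a, b = table[0]
    c, d = table[1]
    r1, c1, n = a + b, a + c, a + b + c + d

    def pmf(k: int) -> float:
        return (
            math.comb(c1, k) * math.comb(n - c1, r1 - k) / math.comb(n, r1)
        )

    p_obs = pmf(a)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-9))


def two_predictor_ols_oracle(x1, x2, y):
    """Coefficient t-test p-values from scratch via the normal equations.

    Written against basic linear-model formulas only (no reuse of the
    package's solver path beyond numpy.linalg.solve).
    """
    from scipy import stats as st

    n = len(y)
    A = np.column_stack([np.ones(n), x1, x2])
    beta = np.linalg.solve(A.T @ A, A.T @ y)
    resid = y - A @ beta
    sigma2 = float(resid @ resid) / (n - 3)
    cov = sigma2 * np.linalg.inv(A.T @ A)
    t = beta / np.sqrt(np.diag(cov))
    p = 2 * st.t.sf(np.abs(t), n - 3)
    return beta[1:], p[1:]
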