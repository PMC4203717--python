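import numpy as np
import pytest

from episcan.synthcohort import SimSpec, simulate_cohort, simulate_cohorts


def ols_pair_oracle(g1, g2, y):
    """Naive 4-column OLS for one pair: (beta_int, se, t, p)."""
    from scipy import stats

    n = y.size
    X = np.column_stack([np.ones(n), g1, g2, g1 * g2])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma2 = resid @ resid / (n - 4)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(cov[3, 3])
    t = beta[3] / se
    return beta[3], se, t, 2 * stats.t.sf(abs(t), n - 4)


@pytest.fixture(scope="session")
def planted_spec():
    """Small cohort spec with one strong planted interaction and an LD block."""
    return SimSpec(
        n_individuals=700,
        n_snps=30,
        interaction_effects={(5, 20): 0.45},
        ld_blocks=((2, 0.95),),
        noise_sd=0.35,
        seed=42,
    )


@pytest.fixture(scope="session")
def planted_cohort(planted_spec):
    return simulate_cohort(planted_spec, "RS-I")


@pytest.fixture(scope="session")
def three_cohorts(planted_spec):
    """Discovery + two filter cohorts sharing the planted effect."""
    return simulate_cohorts(planted_spec, ["RS-I", "RS-II", "RS-III"])


@pytest.fixture(scope="session")
def null_cohort():
    """No genetic effects at all."""
    spec = SimSpec(n_individuals=600, n_snps=25, noise_sd=0.35, seed=99)
    return simulate_cohort(spec, "NULL")
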