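import numpy as np
import pytest

from caqtlkit.synthdata import (
    SimConfig,
    make_ground_truth,
    simulate_peak_counts,
    simulate_genotypes,
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        n_samples=10,
        n_variants=80,
        n_peaks=40,
        ld_block_size=4,
        cell_types={"Tcell": 0.6, "Mono": 0.4},
        mean_depth_per_peak=80.0,
        frac_caqtl_peaks=0.25,
        n_cells_per_sample=100,
        seed=11,
    )


@pytest.fixture(scope="session")
def cohort(small_config):
    genotypes = simulate_genotypes(small_config)
    truth = make_ground_truth(genotypes, small_config)
    tensor = simulate_peak_counts(genotypes, truth, small_config)
    return genotypes, truth, tensor


def oracle_loglik(y, s, g, a, r, pi, psi, delta, lam, phi, theta):
    """Independent joint log-likelihood via scipy.stats distributions.

    NB totals + beta-binomial alt counts at het samples; includes all pmf
    constants (unlike the package's internal objective, which drops the
    binomial coefficient of the BB term).
    """
    from scipy import stats

    mu = s * lam * ((2.0 - g) * (1.0 - pi) + g * pi)
    alpha = 1.0 / phi
    ll = stats.nbinom.logpmf(y, alpha, alpha / (alpha + mu)).sum()
    if len(a):
        p = pi * (1 - psi) / (pi * (1 - psi) + (1 - pi) * psi)
        pp = p * (1 - 2 * delta) + delta
        ll += stats.betabinom.logpmf(a, a + r, pp / theta, (1 - pp) / theta).sum()
    return float(ll)
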