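import numpy as np
import pytest

from snph2 import GenotypeMatrix, Grm, compute_grm, simulate_genotypes


@pytest.fixture(scope="session")
def small_genotypes() -> GenotypeMatrix:
    """A 300 x 120 genotype matrix with block LD, shared across tests."""
    return simulate_genotypes(300, 120, ld_rho=0.6, ld_block_size=12, seed=42)


@pytest.fixture(scope="session")
def small_grm(small_genotypes) -> Grm:
    return compute_grm(small_genotypes)


def simulate_observed_phenotype(grm: Grm, sigma_g: float, sigma_e: float, rng: np.random.Generator) -> np.ndarray:
    """Phenotype drawn from the REML model itself: y ~ N(0, sigma_g*A + sigma_e*I).

    Uses the kernel's spectrum so the genetic values are exactly consistent
    with the fitted covariance structure — the correct oracle for estimator
    calibration checks (no ascertainment, no thresholding).
    """
    d, U = grm.spectrum()
    g = U @ (rng.standard_normal(d.size) * np.sqrt(np.maximum(d, 0) * sigma_g))
    return g + rng.standard_normal(grm.n_samples) * np.sqrt(sigma_e)
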