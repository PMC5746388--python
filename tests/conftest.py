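import numpy as np
import pytest

from netsurv.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A fast cohort: 3 modules x 20 genes + 30 background genes, 60/30 samples."""
    cfg = SimulationConfig(
        n_tumor=60, n_normal=30, n_modules=3, genes_per_module=20,
        n_noise_genes=30, signal_modules=2, signal_genes_per_module=3,
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the package's default study conditions."""
    return simulate_cohort(SimulationConfig(seed=5))


def equicorrelated(rng, n, p, rho):
    """n x p Gaussian block with pairwise correlation rho (single factor)."""
    f = rng.normal(size=(n, 1))
    e = rng.normal(size=(n, p))
    return np.sqrt(rho) * f + np.sqrt(1 - rho) * e
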