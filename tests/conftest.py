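import numpy as np
import pytest

from strainbench import cohort_simulator as sim
from strainbench.deconvolution import FitConfig, fit_mixture


@pytest.fixture(scope="session")
def tiny_cohort():
    """5 participants x 4 samples, 500 sites: small but fully featured."""
    design = sim.build_cohort_design(
        n_participants=5, samples_per_participant=4, n_sites=500, seed=3
    )
    return sim.simulate_cohort(design)


@pytest.fixture(scope="session")
def tiny_fit(tiny_cohort):
    """Reference-engine fit of the tiny cohort (K = 3x true strains)."""
    k = 3 * len(tiny_cohort.genotypes)
    return fit_mixture(tiny_cohort.metagenotypes, FitConfig(n_strains=k, rng_seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
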