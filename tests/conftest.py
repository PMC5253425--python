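import numpy as np
import pytest
from hypothesis import settings

import sibnb

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """An 80-offspring hatchery-style cohort with genotypes and truth."""
    cfg = sibnb.SimConfig(n_females=106, n_males=109, total_offspring=80, seed=1)
    ped = sibnb.simulate_pedigree(cfg)
    gt = sibnb.simulate_genotypes(ped, cfg)
    true_nb = sibnb.pwop_nb(sibnb.ki_vector(ped, ped.offspring_ids))
    return cfg, ped, gt, true_nb


@pytest.fixture(scope="session")
def small_recon(small_cohort):
    """Monogamy reconstruction of the 80-offspring cohort (light search)."""
    _, _, gt, _ = small_cohort
    rc = sibnb.ReconConfig(
        mating_system="monogamy", error_rate=0.01, seed=2, restarts=5, sweeps=30
    )
    return sibnb.reconstruct(gt, rc)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
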