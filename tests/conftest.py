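import numpy as np
import pytest
from hypothesis import settings

from fcrepro import SimConfig, simulate_cohort

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """10 subjects x 2 replicates, one planted effect on 5 pairs (R=10)."""
    cfg = SimConfig(
        n_regions=10,
        n_timepoints=120,
        n_subjects_nc=5,
        n_subjects_pd=5,
        n_replicates=2,
        effect_pairs=(((0, 1, 2, 3, 4), 0.5),),
        sigma_subject=0.08,
        sigma_scan=0.05,
        seed=7,
        dataset_id="toy",
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_scans(small_cohort):
    return small_cohort[0]


@pytest.fixture(scope="session")
def small_truth(small_cohort):
    return small_cohort[1]
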