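import pytest
from hypothesis import HealthCheck, settings

from cfmethyl import SimConfig, simulate_cohort, small_config
from cfmethyl import workflow

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cohort_small():
    """Reduced-genome cohort shared by end-to-end tests."""
    return simulate_cohort(small_config(seed=2))


@pytest.fixture(scope="session")
def quant_small(cohort_small):
    return workflow.quantify_cohort(cohort_small)


@pytest.fixture(scope="session")
def cohort_default():
    """Full-size (20,000-window) cohort at default depth."""
    return simulate_cohort(SimConfig(seed=1))


@pytest.fixture(scope="session")
def quant_default(cohort_default):
    return workflow.quantify_cohort(cohort_default)


@pytest.fixture(scope="session")
def detection_run(quant_small):
    """Detection ensemble (20 members, scaled from 100) on the small cohort."""
    return workflow.train_detector(quant_small, n_mixtures=240, n_members=20,
                                   seed=5)


@pytest.fixture(scope="session")
def subtype_run(quant_small):
    """Subtype ensembles (20 members each) on the small cohort."""
    return workflow.train_subtyper(quant_small, n_mixtures=240, n_members=20,
                                   seed=5)


@pytest.fixture
def tiny_config():
    """Very small config for determinism / round-trip checks."""
    return small_config(seed=9, n_windows=1000, library_size=100_000,
                        n_dmrs=60, n_subtype_dmrs_per_contrast=10,
                        n_qc_windows=30)
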