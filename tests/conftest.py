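import numpy as np
import pytest

from fractamorph import synthetic as syn


@pytest.fixture(scope="session")
def demo_dir(tmp_path_factory):
    """Synthetic input tree + config, shared by the pipeline tests."""
    from fractamorph import pipeline

    root = tmp_path_factory.mktemp("demo")
    config_path = pipeline.make_demo(root, seed=11)
    return root, config_path


@pytest.fixture
def planted_cohort():
    """Rank-1 cohort with a strong planted signal and known saliences."""
    return syn.make_cohort(syn.CohortSpec(
        n_subjects=100, group_sizes=(50, 50), effect=3.0, noise_sd=1.0,
        seed=42))


@pytest.fixture
def support_saliences():
    """Unit-norm saliences supported on the first few features only."""
    sal_img = np.zeros(34)
    sal_img[:6] = 1.0 / np.sqrt(6)
    sal_beh = np.zeros(5)
    sal_beh[:3] = 1.0 / np.sqrt(3)
    return sal_img, sal_beh
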