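import numpy as np
import pytest

from metabotyper.pathways import make_toy_pathway_reference
from metabotyper.simulate import SimConfig, generate_cohort, generate_feature_tables


def small_sim_config(seed: int = 7, n_subjects: int = 120, n_background: int = 120) -> SimConfig:
    cfg = SimConfig(n_subjects=n_subjects, seed=seed)
    for mc in cfg.modes.values():
        mc.n_background_features = n_background
    return cfg


@pytest.fixture(scope="session")
def toy_reference():
    return make_toy_pathway_reference()


@pytest.fixture(scope="session")
def small_cohort():
    """Shared small synthetic cohort (clinical table + ground truth)."""
    cfg = small_sim_config()
    clinical, truth = generate_cohort(cfg)
    return cfg, clinical, truth


@pytest.fixture(scope="session")
def small_tables(small_cohort, toy_reference):
    cfg, _, truth = small_cohort
    return generate_feature_tables(cfg, truth, toy_reference)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
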