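import numpy as np
import pytest

from mvcoclust.data import DataMatrix, FeatureSpec
from mvcoclust.simulate import StudyFixtureConfig, simulate_depression_study


@pytest.fixture(scope="session")
def study_fixture():
    """Full-scale study fixture at the default (3 sd) planted separation."""
    return simulate_depression_study(StudyFixtureConfig(seed=7))


@pytest.fixture(scope="session")
def small_study_fixture():
    """Reduced study fixture for fast end-to-end runs."""
    cfg = StudyFixtureConfig(n_control=20, n_depressed=21, n_fc_features=30,
                             n_questionnaire_features=12, n_categorical=4,
                             n_integer=2, seed=11)
    return simulate_depression_study(cfg)


@pytest.fixture()
def two_cluster_matrix():
    """One numerical feature, 20 subjects each at -5 and +5 (sd 1)."""
    rng = np.random.default_rng(0)
    vals = np.concatenate([rng.normal(-5, 1, 20), rng.normal(5, 1, 20)])[:, None]
    dm = DataMatrix(vals, [f"s{i}" for i in range(40)],
                    [FeatureSpec("x", "numerical")])
    truth = np.repeat([0, 1], 20)
    return dm, truth
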