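import numpy as np
import pytest

from brainclass.simulate import EffectSpec, generate_cohort, generate_feature_table, generate_toy_brain


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def balanced_cohort():
    return generate_cohort((25, 25, 25, 25), n_sites=2, seed=7)


@pytest.fixture(scope="session")
def study_cohort():
    """The reference four-cell design: 55/55/43/40 over four sites."""
    return generate_cohort((55, 55, 43, 40), n_sites=4, age_range=(8, 18), seed=1)


@pytest.fixture(scope="session")
def sphere_fixture():
    """642-vertex sphere of radius 10 mm with 30 straight streamlines."""
    return generate_toy_brain(642, 30, seed=11, radius=10.0)


@pytest.fixture
def null_features(balanced_cohort):
    return generate_feature_table(balanced_cohort, EffectSpec(), n_regions=4, seed=3)
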