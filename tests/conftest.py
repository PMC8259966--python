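import numpy as np
import pytest

from fluctsel.reaction_norms import ReactionNormUni
from fluctsel.synthetic import PUBLISHED_FIXED_EFFECTS, PUBLISHED_VARIANCE_COMPONENTS


@pytest.fixture(scope="session")
def fitted_norm():
    """The quadratic selection reaction norm built from the published fixed effects."""
    return ReactionNormUni(0.0927, -0.0994, -0.0353)


@pytest.fixture(scope="session")
def published_truth():
    """Published point estimates used as generating truth in recovery tests."""
    truth = dict(PUBLISHED_FIXED_EFFECTS)
    truth.update(PUBLISHED_VARIANCE_COMPONENTS)
    return truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
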