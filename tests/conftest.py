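import numpy as np
import pytest

from dyadsync import AnalysisGrid, ScenarioConfig, generate_session


@pytest.fixture(scope="session")
def grid():
    return AnalysisGrid()


@pytest.fixture(scope="session")
def small_session():
    """One 6-trial clean session shared by read-only tests."""
    cfg = ScenarioConfig(n_trials=6, seed=321)
    return generate_session(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
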