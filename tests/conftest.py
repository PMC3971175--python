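import numpy as np
import pytest

from trustinfer import FixtureSpec, TrustConfig, build_self_model, generate_fixture


@pytest.fixture(scope="session")
def default_cfg():
    return TrustConfig()


@pytest.fixture(scope="session")
def trust_model(default_cfg):
    return build_self_model(default_cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def make_fixture():
    def _make(seed=0, **kw):
        kw.setdefault("n_states", 4)
        kw.setdefault("n_observations", 3)
        kw.setdefault("n_controls", 2)
        kw.setdefault("horizon", 1)
        return generate_fixture(FixtureSpec(seed=seed, **kw))

    return _make
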