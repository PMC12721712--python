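import numpy as np
import pytest

from sizersa.core import RDM, ConditionSet
from sizersa.hypotheses import build_hypothesis_rdms
from sizersa.synth import sample_latent_features


@pytest.fixture(scope="session")
def conditions20() -> ConditionSet:
    return sample_latent_features(20, seed=12345)


@pytest.fixture(scope="session")
def hyps20(conditions20):
    return build_hypothesis_rdms(conditions20)


@pytest.fixture
def random_rdm():
    """Factory for random symmetric abs-difference-kind RDMs."""

    def make(n: int, seed: int = 0, kind: str = "abs_difference") -> RDM:
        rng = np.random.default_rng(seed)
        m = rng.random((n, n))
        m = m + m.T
        np.fill_diagonal(m, 0.0)
        ids = tuple(f"c{i}" for i in range(n))
        return RDM(ids=ids, values=m, kind=kind)

    return make
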