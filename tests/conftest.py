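import numpy as np
import pytest

from ssadrive import GermlineParams, ZygoticParams
from ssadrive.alleles import ALLELE_ORDER


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def calibrated_params():
    """Default calibrated cutting parameters, no excision."""
    return GermlineParams(q=0.95, p=0.78, delta=0.4)


@pytest.fixture
def excision_params():
    """Calibrated cutting plus 10% female excision, full marker retention."""
    return GermlineParams(
        q=0.95, p=0.78, delta=0.4, alpha_female=0.1, alpha_male=0.01, epsilon=1.0
    )


@pytest.fixture
def no_zygotic():
    return ZygoticParams()


def assert_distribution(dist, expected: dict, atol=1e-12):
    """Compare an AlleleDistribution against a state->prob mapping."""
    got = {a: dist[a] for a in ALLELE_ORDER}
    for state in ALLELE_ORDER:
        assert got[state] == pytest.approx(expected.get(state, 0.0), abs=atol), state
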