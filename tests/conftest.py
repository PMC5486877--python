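import pytest

from regmean import (CANONICAL_SPEC, SKLAR_SPEC,
                     simulate_linear_common_source)


@pytest.fixture(scope="session")
def canonical_sample_200():
    """One n=200 draw from the canonical common-source model."""
    return simulate_linear_common_source(CANONICAL_SPEC, 200, seed=12345)


@pytest.fixture(scope="session")
def canonical_sample_large():
    """A large draw for moment-convergence checks."""
    return simulate_linear_common_source(CANONICAL_SPEC, 1_000_000, seed=7)


@pytest.fixture(scope="session")
def sklar_sample_large():
    return simulate_linear_common_source(SKLAR_SPEC, 1_000_000, seed=11)
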