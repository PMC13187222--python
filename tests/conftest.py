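import numpy as np
import pytest

from scalenet.cfa import CfaSpec
from scalenet.pipeline import make_fixture


@pytest.fixture(scope="session")
def two_factor_matrix():
    """Invariant two-factor fixture (12+6 items, n=500/500), shared per session."""
    matrix, truth = make_fixture("two_factor_invariant", seed=20260927)
    return matrix, truth


@pytest.fixture(scope="session")
def two_factor_spec():
    return CfaSpec(
        factor_map={
            "integration": [f"IP{i}" for i in range(1, 13)],
            "stability": [f"IP{i}" for i in range(13, 19)],
        }
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
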