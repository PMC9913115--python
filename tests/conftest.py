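import numpy as np
import pytest

from romma import CoefficientSet, generate_exact_fixture
from romma.evaluate import build_contingency


@pytest.fixture(scope="session")
def coeffs():
    return CoefficientSet.default()


@pytest.fixture(scope="session")
def exact_fixture(coeffs):
    """The deterministic 355-patient table-exact cohort (expensive-ish: build once)."""
    return generate_exact_fixture(coeffs)


@pytest.fixture(scope="session")
def exact_table(exact_fixture, coeffs):
    return build_contingency(exact_fixture, coeffs)


@pytest.fixture()
def rng():
    return np.random.default_rng(20230131)
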