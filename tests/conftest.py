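import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from episcan.core_data import (  # noqa: E402
    BINARY,
    BINARY_TRAIT,
    QUANTITATIVE,
    GenotypeMatrix,
    PhenotypeVector,
)


def make_genotypes(codes, alphabet=None):
    codes = np.asarray(codes, dtype=np.int8)
    if alphabet is None:
        alphabet = "triallelic" if (codes == 2).any() else BINARY
    m, n = codes.shape
    return GenotypeMatrix(
        codes, [f"s{i}" for i in range(m)], [f"i{s}" for s in range(n)], alphabet
    )


def make_phenotype(values, kind=None):
    values = np.asarray(values, dtype=float)
    if kind is None:
        kind = BINARY_TRAIT if set(np.unique(values)) <= {0.0, 1.0} else QUANTITATIVE
    return PhenotypeVector(values, kind, [f"i{s}" for s in range(values.size)])


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
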