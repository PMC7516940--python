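import numpy as np
import pytest

import rsdarma as rd


@pytest.fixture(scope="session")
def dna_range():
    return rd.DNA_RANGE


@pytest.fixture(scope="session")
def cloud_range():
    return rd.CLOUDINESS_RANGE


@pytest.fixture(scope="session")
def range4():
    return rd.CategoricalRange(("s0", "s1", "s2", "s3"))


@pytest.fixture(scope="session")
def dna_model():
    return rd.dna_three_regime_model()


@pytest.fixture(scope="session")
def cloud2_model():
    return rd.cloudiness_two_regime_model()


@pytest.fixture(scope="session")
def cloud3_model():
    return rd.cloudiness_three_regime_model()


@pytest.fixture(scope="session")
def two_regime_truth(range4):
    """Known two-regime marginal RS-DAR(1) used for recovery studies."""
    part = rd.RangePartition.from_blocks(range4, [("s0", "s1"), ("s2", "s3")])
    return rd.RsDar1Spec.marginal(
        range4, part, 0.5,
        [[0.5, 0.2, 0.2, 0.1], [0.1, 0.2, 0.2, 0.5]])


def random_pmf(gen: np.random.Generator, n: int, floor: float = 0.02) -> np.ndarray:
    p = gen.dirichlet(np.ones(n))
    p = np.clip(p, floor, None)
    return p / p.sum()
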