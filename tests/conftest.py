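import numpy as np
import pytest

from rocpv import LabeledScores


@pytest.fixture
def tiny_data() -> LabeledScores:
    """Four subjects: cases score {3, 5}, controls {1, 4}; AUROC 3/4."""
    return LabeledScores([3, 5, 1, 4], [1, 1, 0, 0])


@pytest.fixture
def perfect_data() -> LabeledScores:
    """All case scores strictly above all control scores."""
    rng = np.random.default_rng(0)
    controls = rng.normal(0, 1, 50)
    cases = rng.normal(10, 1, 50)
    return LabeledScores(np.concatenate([cases, controls]),
                         np.concatenate([np.ones(50), np.zeros(50)]))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
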