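import numpy as np
import pytest

from parsyn.tasks import PatternSet, generate_patterns


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_task():
    return generate_patterns(n_axons=3, n_patterns=8, seed=7)


@pytest.fixture
def xor_task():
    """Four near-corner points with XOR labels: unsolvable by any monotone
    additive model (raising either coordinate must raise the somatic drive,
    but XOR requires the two mixed corners to outrank both pure corners)."""
    inputs = np.array(
        [[0.01, 0.01], [0.01, 0.99], [0.99, 0.01], [0.99, 0.99]]
    )
    labels = np.array([-1.0, 1.0, 1.0, -1.0])
    return PatternSet(inputs, labels)
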