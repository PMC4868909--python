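import numpy as np
import pytest

from tswta.cell import DisparityCellState, init_receptive_field
from tswta.synth import make_pattern_set


@pytest.fixture(scope="session")
def pattern_set():
    """The 8-pattern training set: 4 disparities + complements, 9x9."""
    return make_pattern_set(9, 9, 4, seed=7)


@pytest.fixture(scope="session")
def probes(pattern_set):
    return sorted(
        (p for p in pattern_set if not p.is_complement), key=lambda p: p.disparity
    )


@pytest.fixture()
def fresh_cell():
    return DisparityCellState(rf=init_receptive_field(9, 9, seed=42))
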