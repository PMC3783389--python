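import numpy as np
import pytest

from mircleave import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(20130925)


@pytest.fixture
def small_transcriptome():
    return syn.gen_transcriptome(5, (300, 400), 0.45, seed=42)
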