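import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_layout():
    from segmix.genome import GenomeLayout

    return GenomeLayout(("chr1", "chr2"), (250, 140), resolution=10, chunk_size=10)
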