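import numpy as np
import pytest
from hypothesis import settings

import florasm.simulate as sim

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_txome() -> sim.SyntheticTranscriptome:
    return sim.generate_transcriptome(5, (400, 1200), seed=101)


@pytest.fixture(scope="session")
def tiling_pairs(small_txome):
    return sim.tile_paired_reads(small_txome, depth=15)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
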