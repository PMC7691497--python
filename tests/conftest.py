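import numpy as np
import pytest

from matdecay.io_formats import SequenceSet
from matdecay.synthetic_data import SynthConfig, gen_sequences

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, length))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_synth():
    """One small synthetic dataset shared by read-only tests."""
    cfg = SynthConfig(
        seed=11,
        n_genes=200,
        n_smallrnas=300,
        n_lncrnas=40,
        n_scrambled_decoys=20,
        n_zga_genes=50,
        n_replicates=10,
    )
    return cfg, gen_sequences(cfg)


@pytest.fixture
def tiny_transcripts(rng):
    return SequenceSet({f"t{i}": random_seq(rng, 120) for i in range(8)})
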