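import numpy as np
import pytest

from mtrkit.synthetic_data import SyntheticConfig, generate_transcripts
from mtrkit.transcript_model import Transcript


@pytest.fixture
def atg_repeat():
    """Ten methionine codons plus a terminal stop."""
    return Transcript("ATG10", "ATG" * 10 + "TAA")


@pytest.fixture
def random_transcript():
    """One seeded random transcript of 80 residues."""
    cfg = SyntheticConfig(n_genes=1, protein_length=(80, 80), seed=11)
    return generate_transcripts(cfg)[0]


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
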