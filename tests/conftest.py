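import numpy as np
import pytest

from gcstruct.io import ProteinRecord


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(20240917))


def make_annotated(pairs):
    """Build ProteinRecords from (sequence, ss_string) pairs."""
    return [
        ProteinRecord(protein_id=f"p{i + 1}", sequence=seq, ss_string=ss)
        for i, (seq, ss) in enumerate(pairs)
    ]


@pytest.fixture
def tiny_proteome():
    # 4 residues: A in helix twice, G in coil twice
    return make_annotated([("AAGG", "HHCC")])


def random_ss_string(rng, length):
    return "".join(rng.choice(list("HEC"), size=length))
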