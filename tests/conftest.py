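import numpy as np
import pytest

from rbskit.seqcore import Alignment, GappedRow, Sequence


@pytest.fixture
def family_alignment() -> Alignment:
    """Six-row toy alignment with conserved columns and gapped positions."""
    rows = [
        GappedRow("r1", "MLLVA-DEEL"),
        GappedRow("r2", "MLLVA-DEEL"),
        GappedRow("r3", "MLLVAADEEL"),
        GappedRow("r4", "MVLVAADEEL"),
        GappedRow("r5", "MVLVA-DEEL"),
        GappedRow("r6", "ML-VA-DEEL"),
    ]
    return Alignment(rows)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_protein(
    rng: np.random.Generator, length: int, alphabet: str = "ACDEFGHIKLMNPQRSTVWY"
) -> Sequence:
    return Sequence("rnd", "".join(rng.choice(list(alphabet), size=length)))
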