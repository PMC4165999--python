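import numpy as np
import pytest

from dnabind.seqio import AMINO_ACIDS, ProteinRecord


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def small_records() -> list[ProteinRecord]:
    return [
        ProteinRecord("a", "first", "MKVLAWGHE" * 10),
        ProteinRecord("b", "second", "ACDEFGHIKLMNPQRSTVWY" * 5),
        ProteinRecord("c", "third", "GGGGSSSSPP" * 8),
    ]
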