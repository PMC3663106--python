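import numpy as np
import pytest

from asmlik.io_formats import AssemblyIndex, Contig


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))


def random_genome(rng: np.random.Generator, lengths: list[int], prefix: str = "c") -> AssemblyIndex:
    return AssemblyIndex(
        [Contig(f"{prefix}{i + 1}", random_sequence(rng, n)) for i, n in enumerate(lengths)]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_genome(rng):
    """Two-contig toy genome, 120 + 80 bp."""
    return random_genome(rng, [120, 80])
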