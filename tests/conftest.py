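import numpy as np
import pytest

from creascan.motifs import default_motifs, parse_motif


@pytest.fixture(scope="session")
def motif_set():
    """The eight built-in motifs (repressor site, sub-motifs, activators)."""
    return default_motifs()


@pytest.fixture
def syggcg():
    return parse_motif("SYGGGG", "SYGGGG")


@pytest.fixture
def arar_motif():
    # Longest ungapped built-in motif: low spontaneous background rate,
    # the marker of choice for planted-recovery scenarios.
    return parse_motif("AraR", "CGG[AGT]TAA[AT]")


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def random_dna(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
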