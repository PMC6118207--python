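import numpy as np
import pytest

from tigerpart.alignment import AlignmentMatrix


@pytest.fixture
def small_aln() -> AlignmentMatrix:
    """4 taxa x 6 sites with one invariable, variable and missing column."""
    return AlignmentMatrix.from_sequences(
        ["t1", "t2", "t3", "t4"],
        ["ACGTA?", "ACCTAC", "AGCAAC", "AGCA-C"],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_alignment(rng, n_taxa: int, n_sites: int,
                     missing_prob: float = 0.1) -> AlignmentMatrix:
    """Random DNA matrix with occasional missing symbols."""
    states = np.array(list("ACGT?-N"))
    probs = np.array([1, 1, 1, 1, 0, 0, 0], dtype=float)
    probs[4:] = missing_prob * 4 / 3 / (1 - missing_prob) if missing_prob else 0
    probs /= probs.sum()
    mat = rng.choice(states, size=(n_taxa, n_sites), p=probs)
    taxa = [f"t{i}" for i in range(n_taxa)]
    return AlignmentMatrix(tuple(taxa), mat)
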