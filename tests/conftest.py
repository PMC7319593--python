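import numpy as np
import pytest

from acrpred import (
    BLAST_COLUMN_ORDER,
    ProteinRecord,
    PSSMatrix,
    gen_pssm,
    gen_protein,
)
from acrpred.fixtures import golden_dataset

#: Coarse power-of-two sub-grid spanning the low-gamma regime needed for
#: high-dimensional standardized features; keeps protocol tests fast.
FAST_GRID = (-10, -8, 0, 4)


@pytest.fixture(scope="session")
def golden():
    """Pinned golden fixture: (dataset, records, pssms)."""
    return golden_dataset()


@pytest.fixture(scope="session")
def small_pair():
    """One L=60 record with a matching random PSSM."""
    rec = gen_protein(60, seed=11)
    return rec, gen_pssm(rec, seed=12)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_pssm(rng, L, protein_id="p", low=-10, high=10):
    """Random integer PSSM paired with a random sequence of length L."""
    seq = "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, size=L))
    scores = rng.integers(low, high + 1, size=(L, 20))
    return (
        ProteinRecord(protein_id, "", seq),
        PSSMatrix(protein_id, scores, seq, column_order=BLAST_COLUMN_ORDER),
    )
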