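import numpy as np
import pytest

from ppigray.io_formats import AMINO_ALPHABET, GeneRecord, ProteinRecord, Pssm
from ppigray.synthetic_fixtures import FixtureConfig, generate


def random_protein(rng: np.random.Generator, length: int, pid: str = "p") -> ProteinRecord:
    residues = "".join(rng.choice(list(AMINO_ALPHABET), size=length))
    return ProteinRecord(id=pid, residues=residues)


def random_gene(rng: np.random.Generator, length: int, gid: str = "g") -> GeneRecord:
    return GeneRecord(id=gid, nucleotides="".join(rng.choice(list("ACGT"), size=length)))


def random_pssm(rng: np.random.Generator, length: int, pid: str = "p") -> Pssm:
    scores = rng.integers(-8, 13, size=(length, 20)).astype(float)
    return Pssm(protein_id=pid, scores=scores)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_fixture_set():
    """A tiny deterministic synthetic study shared across tests."""
    config = FixtureConfig(n_proteins=16, length_range=(60, 120), seed=11,
                           effect_size=8.0)
    return generate(config, max_pairs=80)
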