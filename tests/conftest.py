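import numpy as np
import pytest
from importlib import resources

from prionscan import (
    FixtureSpec,
    ProteinRecord,
    ScoringConfig,
    load_propensity_table,
    read_fasta,
)
from prionscan.fixtures import generate_proteome


@pytest.fixture(scope="session")
def table():
    return load_propensity_table()


@pytest.fixture(scope="session")
def config():
    return ScoringConfig()


@pytest.fixture(scope="session")
def hnrnpa1():
    """The two hnRNPA1 isoform records (long 372 aa, short 320 aa)."""
    path = resources.files("prionscan.data") / "hnrnpa1_isoforms.fasta"
    return read_fasta(str(path))


@pytest.fixture(scope="session")
def small_spec():
    return FixtureSpec(seed=7, n_proteins=20)


@pytest.fixture(scope="session")
def small_proteome(small_spec):
    return generate_proteome(small_spec)


def random_protein(rng: np.random.Generator, min_len=41, max_len=500) -> ProteinRecord:
    """A random protein: half drawn uniformly over the 20 residues, half
    from block-structured compositions, for oracle-equivalence sweeps."""
    from prionscan.fixtures import load_block_alphabets

    length = int(rng.integers(min_len, max_len + 1))
    if rng.random() < 0.5:
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
    else:
        alphabets = load_block_alphabets()
        kinds = list(alphabets)
        parts = []
        remaining = length
        while remaining > 0:
            block_len = int(min(remaining, rng.integers(20, 120)))
            residues, weights = alphabets[kinds[int(rng.integers(len(kinds)))]]
            parts.append(
                "".join(rng.choice(list(residues), size=block_len, p=weights))
            )
            remaining -= block_len
        seq = "".join(parts)
    return ProteinRecord(accession=f"RND{rng.integers(1 << 30)}", sequence=seq)
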