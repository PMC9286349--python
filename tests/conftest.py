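import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from splicebench import Proteome, ProteinEntry, build_index
from splicebench.proteome import COLLAPSED_AA


def random_entries(rng, n_max=20, len_max=100, n_min=1, len_min=10):
    """Random (accession, sequence) pairs over the 19-letter alphabet."""
    n = int(rng.integers(n_min, n_max + 1))
    entries = []
    for i in range(n):
        L = int(rng.integers(len_min, len_max + 1))
        entries.append(
            (f"P{i + 1}", "".join(rng.choice(list(COLLAPSED_AA), size=L)))
        )
    return entries


def as_proteome(entries, il_collapsed=True):
    return Proteome([ProteinEntry(a, s) for a, s in entries], il_collapsed=il_collapsed)


@pytest.fixture
def toy_proteome():
    """One protein used across mapper examples."""
    return as_proteome([("P1", "MKLLPETGAL")], il_collapsed=False)


@pytest.fixture
def toy_index(toy_proteome):
    return build_index(toy_proteome)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def stitched_peptide(rng, entries):
    """8-15-mer stitched from two random proteome pieces (clamped to fit)."""
    L = int(rng.integers(8, 16))
    seq = entries[int(rng.integers(len(entries)))][1]
    s = min(int(rng.integers(1, L)), len(seq))
    i = int(rng.integers(0, len(seq) - s + 1))
    seq2 = entries[int(rng.integers(len(entries)))][1]
    want = min(L - s, len(seq2))
    j = int(rng.integers(0, len(seq2) - want + 1))
    return seq[i : i + s] + seq2[j : j + want]
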