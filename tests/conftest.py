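import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/util.py


@pytest.fixture
def rng():
    return np.random.default_rng(20220628)


@pytest.fixture
def toy_matrix_tsv(tmp_path):
    """5 taxa x 6 characters with one missing cell and one uninformative
    column."""
    text = ("A\t1\t1\t0\t1\t1\t0\n"
            "B\t1\t1\t0\t0\t1\t0\n"
            "C\t0\t0\t1\t0\t0\t0\n"
            "D\t0\t?\t1\t0\t0\t0\n"
            "E\t0\t0\t1\t0\t1\t0\n")
    p = tmp_path / "toy.tsv"
    p.write_text(text)
    return p


@pytest.fixture
def emergent_loci():
    """Five-taxon loci whose unique quartet-score optimum contains the
    clade {A,B} although no locus cleanly resolves it (hidden/emergent
    support)."""
    from util import split_locus
    return [split_locus(1, "ABC", "DE"), split_locus(2, "ABD", "CE"),
            split_locus(3, "ABE", "CD"), split_locus(4, "CD", "ABE")]


@pytest.fixture
def house_of_cards_loci():
    """Six-taxon fixture (found by exhaustive search): the unique optimum
    (a,((b,f),((c,d),e))) holds clade {c,d} with no clean supporting
    locus; removing the two top-PCS loci (acd|bef, aef|bcd) collapses
    {c,d} together with {b,f} and {c,d,e}."""
    from util import split_locus
    sides = [(1, "acd"), (2, "ac"), (3, "abf"), (4, "abf"),
             (5, "aef"), (6, "df"), (7, "df")]
    taxa = set("abcdef")
    return [split_locus(i, sorted(s), sorted(taxa - set(s)))
            for i, s in sides]
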