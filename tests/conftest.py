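import numpy as np
import pytest

from vegfsurvey.seqio import Alignment, CodonAlignment, SequenceRecord, parse_newick


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def four_taxon_tree():
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def toy_codon_alignment():
    records = [
        SequenceRecord(id="A", residues="ACTGGG"),
        SequenceRecord(id="B", residues="GCAGGG"),
        SequenceRecord(id="C", residues="ACTGGA"),
        SequenceRecord(id="D", residues="ACTGGG"),
    ]
    return CodonAlignment(alignment=Alignment(records=records, alphabet="nucleotide"))
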