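import numpy as np
import pytest

from cdr3profile.io import Group, Rearrangement, Repertoire
from cdr3profile.translate import translate_repertoire

# 61 sense codons for random in-frame junction construction in tests
BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = [a + b + c for a in BASES for b in BASES for c in BASES
                if a + b + c not in STOPS]


def make_repertoire(clones, sample_id="S", group=Group.UNLABELED,
                    translated=True):
    """Build a repertoire from (cdr3_nt, templates) pairs."""
    rep = Repertoire.from_rearrangements(
        sample_id,
        (Rearrangement(cdr3_nt=nt, templates=t, sample_id=sample_id)
         for nt, t in clones),
        group=group,
    )
    if translated:
        translate_repertoire(rep)
    return rep


def random_inframe_junction(rng, n_codons):
    """C...F junction with uniform sense-codon interior."""
    interior = "".join(SENSE_CODONS[i] for i in
                       rng.integers(0, len(SENSE_CODONS), size=n_codons - 2))
    return "TGT" + interior + "TTT"


@pytest.fixture
def rng():
    return np.random.default_rng(20230825)
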