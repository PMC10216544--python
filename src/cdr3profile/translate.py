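"""CDR3 junction translation and productivity classification.

A CDR3 junction runs from the first base of the conserved V-gene cysteine
codon through the last base of the conserved J-gene phenylalanine (or
tryptophan) codon, so a well-formed productive junction translates to a
peptide of the form C...F/W.  A rearrangement is *productive* when the
junction is in frame (length divisible by 3) and its translation carries no
stop codon; anchor conservation is reported but never used as a filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio.Seq import Seq

from .io import Cohort, FrameStatus, Rearrangement, Repertoire

log = logging.getLogger(__name__)

_VALID_NT = frozenset("ACGT")


@dataclass(frozen=True)
class TranslationResult:
    cdr3_aa: str
    has_stop: bool
    in_frame: bool
    anchors_ok: bool


def translate_cdr3(cdr3_nt: str) -> TranslationResult:
    """Translate a junction with the standard genetic code.

    Complete codons are read from position 1; a trailing partial codon is
    ignored for the amino acid string and flagged through ``in_frame=False``.
    Stop codons appear as ``*`` in the returned string.
    """
    if not cdr3_nt:
        raise ValueError("empty nucleotide sequence")
    nt = cdr3_nt.upper()
    bad = set(nt) - _VALID_NT
    if bad:
        raise ValueError(f"non-ACGT character(s) {sorted(bad)} in {cdr3_nt!r}")
    ncodons = len(nt) // 3
    aa = str(Seq(nt[: 3 * ncodons]).translate())
    anchors_ok = len(aa) >= 2 and aa[0] == "C" and aa[-1] in "FW"
    return TranslationResult(
        cdr3_aa=aa,
        has_stop="*" in aa,
        in_frame=len(nt) % 3 == 0,
        anchors_ok=anchors_ok,
    )


def classify_productive(r: Rearrangement) -> bool:
    """Decide productivity and cache translation results on the record.

    Productive = in frame AND stop-free.  A frame annotation carried by the
    input file takes precedence over the recomputed frame; disagreements
    between the two are logged but the file wins, so that vendor-side
    filtering decisions remain reproducible.  The computed translation is
    always stored on the record (it is the single source of truth for
    downstream biochemistry), cross-checked against any input amino acid
    string.
    """
    tr = translate_cdr3(r.cdr3_nt)
    if r.cdr3_aa is not None and r.cdr3_aa != tr.cdr3_aa:
        log.warning(
            "sample %s: input amino_acid %r disagrees with translation %r "
            "of %s; using the translation",
            r.sample_id, r.cdr3_aa, tr.cdr3_aa, r.cdr3_nt,
        )
    r.cdr3_aa = tr.cdr3_aa

    computed_status = (
        FrameStatus.STOP if (tr.in_frame and tr.has_stop)
        else FrameStatus.IN_FRAME if tr.in_frame
        else FrameStatus.OUT_OF_FRAME
    )
    status = r.frame_status
    if status is None:
        status = computed_status
    elif status is not computed_status:
        log.warning(
            "sample %s: file frame annotation %s disagrees with computed %s "
            "for %s; file annotation wins",
            r.sample_id, status.value, computed_status.value, r.cdr3_nt,
        )
    r.frame_status = status
    r.productive = status is FrameStatus.IN_FRAME and not tr.has_stop
    return r.productive


def translate_repertoire(rep: Repertoire) -> Repertoire:
    """Translate and classify every rearrangement in place."""
    for r in rep.rearrangements:
        classify_productive(r)
    return rep


def translate_cohort(cohort: Cohort) -> Cohort:
    for rep in cohort.repertoires:
        translate_repertoire(rep)
    return cohort


def productive(rep: Repertoire) -> list[Rearrangement]:
    """The repertoire's productive records, classifying lazily if needed."""
    out = []
    for r in rep.rearrangements:
        if r.productive is None:
            classify_productive(r)
        if r.productive:
            out.append(r)
    return out
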