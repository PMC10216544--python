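"""Enrichment-based class I pMHC immunogenicity scoring of CDR3 peptides.

A peptide's score is the sum, over unmasked positions, of a per-residue
log-enrichment weight times a per-position importance weight.  Positions 1,
2 and the C-terminal position are masked by default: in a presented 9-mer
they are MHC anchor positions and contribute little to T-cell recognition.
Peptides scoring strictly above zero are classified immunogenic
("positive"); a score of exactly 0 is non-positive.

The default weight table ships with the package (``data/
immunogenicity_weights.tsv``); every operation accepts a substitute model.
The importance map is calibrated on 9-mers; for longer peptides the first
five positions map from the N-terminus, the last four from the C-terminus,
and any extra interior positions reuse the central-position weight — a
documented extrapolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .biochem import STANDARD_RESIDUES

#: sentinel usable in a mask to denote the C-terminal position
CTERM = -1

_CENTRAL_POSITION = 5  # 1-based position whose importance is reused for
                       # interior positions of peptides longer than 9


@dataclass(frozen=True)
class ImmunogenicityModel:
    enrichment: dict[str, float]
    importance: tuple[float, ...]  # per 9-mer position, 1-based order
    default_mask: tuple[int, ...] = (1, 2, CTERM)

    def __post_init__(self) -> None:
        missing = STANDARD_RESIDUES - set(self.enrichment)
        if missing:
            raise ValueError(f"enrichment table missing residues {sorted(missing)}")

    def position_weight(self, pos: int, length: int) -> float:
        """Importance of 1-based position ``pos`` in a peptide of ``length``.

        Exact for 9-mers; the mapping for other lengths is
        C-terminus-aligned for the last four positions, N-terminus-aligned
        for the first five, central-weight for anything between.
        """
        k = len(self.importance)
        from_end = length - pos  # 0 for the C-terminal residue
        if from_end < 4:
            return self.importance[k - 1 - from_end]
        if pos <= _CENTRAL_POSITION:
            return self.importance[pos - 1]
        return self.importance[_CENTRAL_POSITION - 1]


@dataclass(frozen=True)
class ImmunogenicityScore:
    cdr3_aa: str
    score: float

    @property
    def positive(self) -> bool:
        return self.score > 0.0


def load_default_model() -> ImmunogenicityModel:
    path = resources.files("cdr3profile").joinpath("data/immunogenicity_weights.tsv")
    return load_model(path)


def load_model(path) -> ImmunogenicityModel:
    """Read a weight TSV: rows of ``residue <aa> <weight>`` and
    ``position <1-based index> <weight>``."""
    enrichment: dict[str, float] = {}
    importance: dict[int, float] = {}
    with open(str(path)) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            kind, key, value = line.split("\t")
            if kind == "residue":
                enrichment[key] = float(value)
            elif kind == "position":
                importance[int(key)] = float(value)
            else:
                raise ValueError(f"unknown row kind {kind!r} in weight file")
    imp = tuple(importance[i] for i in sorted(importance))
    return ImmunogenicityModel(enrichment=enrichment, importance=imp)


def _resolve_mask(mask: Sequence[int], length: int) -> frozenset[int]:
    return frozenset(length if m == CTERM else m for m in mask)


def score_peptide(
    cdr3_aa: str,
    model: ImmunogenicityModel | None = None,
    mask: Sequence[int] | None = None,
) -> ImmunogenicityScore:
    """Score one whole peptide.

    ``mask`` is a sequence of 1-based positions to exclude (:data:`CTERM`
    denotes the last position); the model default masks 1, 2 and the
    C-terminus.  Peptides shorter than 3 residues cannot be scored — the
    default mask would cover everything.
    """
    model = model or load_default_model()
    seq = cdr3_aa.upper()
    if len(seq) < 3:
        raise ValueError(f"peptide {cdr3_aa!r} shorter than 3 residues")
    bad = set(seq) - STANDARD_RESIDUES
    if bad:
        raise ValueError(f"unknown residue(s) {sorted(bad)} in {cdr3_aa!r}")
    masked = _resolve_mask(model.default_mask if mask is None else mask, len(seq))
    score = 0.0
    for pos, res in enumerate(seq, start=1):
        if pos in masked:
            continue
        score += model.enrichment[res] * model.position_weight(pos, len(seq))
    return ImmunogenicityScore(cdr3_aa=seq, score=score)


def score_peptide_kmer(
    cdr3_aa: str,
    model: ImmunogenicityModel | None = None,
    k: int = 9,
) -> ImmunogenicityScore:
    """Alternative sliding-window mode: max whole-window score over all
    k-mers (the peptide itself if shorter than k)."""
    model = model or load_default_model()
    seq = cdr3_aa.upper()
    if len(seq) <= k:
        return score_peptide(seq, model)
    best = max(
        score_peptide(seq[i:i + k], model).score for i in range(len(seq) - k + 1)
    )
    return ImmunogenicityScore(cdr3_aa=seq, score=best)


@dataclass(frozen=True)
class ImmunogenicitySummary:
    sample_id: str
    positive_count: int
    total_count: int
    percent_positive: float  # reported to two decimals


def summarize_immunogenicity(
    scores: Iterable[ImmunogenicityScore], sample_id: str = ""
) -> ImmunogenicitySummary:
    """Per-sample positive fraction, as a percentage to two decimals."""
    scores = list(scores)
    if not scores:
        raise ValueError("empty score collection")
    pos = sum(1 for s in scores if s.positive)
    return ImmunogenicitySummary(
        sample_id=sample_id,
        positive_count=pos,
        total_count=len(scores),
        percent_positive=round(100.0 * pos / len(scores), 2),
    )


def variance_f_test(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided F-test for equality of score variances between groups.

    The choice of variance test is method-dependent (none is canonical for
    this comparison); the F ratio is reported with larger variance in the
    numerator.  Returns (F, p).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two scores per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va >= vb:
        F, dfn, dfd = va / vb, len(a) - 1, len(b) - 1
    else:
        F, dfn, dfd = vb / va, len(b) - 1, len(a) - 1
    p = 2.0 * stats.f.sf(F, dfn, dfd)
    return float(F), float(min(p, 1.0))
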