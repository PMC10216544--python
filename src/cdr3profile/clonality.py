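"""Simpson clonality of a clone-frequency distribution.

Clone frequencies are productive template fractions p_i.  Simpson's index
is the plug-in sum of squared frequencies, Simpson's diversity its
complement, and Simpson clonality the square root of the index:

    clonality = sqrt(sum_i p_i**2),    0 < clonality <= 1

A perfectly even sample of n clones gives 1/sqrt(n) (approaching 0); a
monoclonal sample gives exactly 1.  No small-sample (n(n-1)) bias
correction is applied: the statistic describes the evenness of the sample
itself, not of the underlying T-cell pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import Repertoire
from .translate import productive


@dataclass(frozen=True)
class ClonalitySummary:
    sample_id: str
    n_clones: int
    simpson_index: float
    simpson_diversity: float
    clonality: float


def clone_frequencies(
    rep: Repertoire, productive_only: bool = True
) -> list[tuple[str, float]]:
    """Per-clone frequencies p_i = templates_i / total templates.

    By default only productive rearrangements enter the numerator and the
    denominator ("productive Simpson clonality").
    """
    records = productive(rep) if productive_only else rep.rearrangements
    total = sum(r.templates for r in records)
    if total == 0:
        raise ValueError(
            f"sample {rep.sample_id}: no "
            f"{'productive ' if productive_only else ''}templates"
        )
    return [(r.cdr3_nt, r.templates / total) for r in records if r.templates > 0]


def simpson_clonality(
    freqs: Iterable[float] | Sequence[tuple[str, float]],
    sample_id: str = "",
) -> ClonalitySummary:
    """Simpson index/diversity/clonality from frequencies summing to 1."""
    p = [f[1] if isinstance(f, tuple) else float(f) for f in freqs]
    if not p:
        raise ValueError("no clone frequencies")
    total = math.fsum(p)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"clone frequencies sum to {total!r}, not 1")
    index = math.fsum(x * x for x in p)
    return ClonalitySummary(
        sample_id=sample_id,
        n_clones=len(p),
        simpson_index=index,
        simpson_diversity=1.0 - index,
        clonality=math.sqrt(index),
    )


def sample_clonality(rep: Repertoire, productive_only: bool = True) -> ClonalitySummary:
    return simpson_clonality(
        clone_frequencies(rep, productive_only=productive_only),
        sample_id=rep.sample_id,
    )
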