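"""Per-sample CDR3 length distributions and moment summaries.

Lengths are measured on the nucleotide junction by default (the scale the
sequencer reports; always a multiple of 3 for in-frame junctions) or on the
translated peptide.  Only productive rearrangements contribute, and each
clone enters with weight ``templates / total productive templates`` — the
"sum productive frequency" convention — so the distribution sums to 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Repertoire
from .translate import productive

log = logging.getLogger(__name__)


@dataclass
class LengthDistribution:
    scale: str  # "nt" or "aa"
    lengths: list[int] = field(default_factory=list)
    frequencies: list[float] = field(default_factory=list)
    unique_counts: list[int] = field(default_factory=list)

    @property
    def min_length(self) -> int | None:
        return min(self.lengths) if self.lengths else None

    @property
    def max_length(self) -> int | None:
        return max(self.lengths) if self.lengths else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "length": self.lengths,
            "frequency": self.frequencies,
            "unique_count": self.unique_counts,
        })


@dataclass(frozen=True)
class LengthSummary:
    mean: float
    variance: float
    skewness: float
    kurtosis: float  # excess: normal distribution -> 0
    weighted: bool


def length_distribution(rep: Repertoire, scale: str = "nt") -> LengthDistribution:
    """Template-frequency-weighted length histogram of productive clones."""
    if scale not in ("nt", "aa"):
        raise ValueError(f"scale must be 'nt' or 'aa', got {scale!r}")
    prods = productive(rep)
    total = sum(r.templates for r in prods)
    if total == 0:
        log.warning("sample %s: no productive templates; empty length "
                    "distribution", rep.sample_id)
        return LengthDistribution(scale=scale)
    freq: dict[int, float] = {}
    uniq: dict[int, int] = {}
    for r in prods:
        L = len(r.cdr3_nt) if scale == "nt" else len(r.cdr3_aa)
        freq[L] = freq.get(L, 0.0) + r.templates / total
        uniq[L] = uniq.get(L, 0) + 1
    lengths = sorted(freq)
    return LengthDistribution(
        scale=scale,
        lengths=lengths,
        frequencies=[freq[L] for L in lengths],
        unique_counts=[uniq[L] for L in lengths],
    )


def length_summary(dist: LengthDistribution, weighted: bool = True) -> LengthSummary:
    """Population moments of the length distribution.

    ``weighted=True`` weights each length by its sum productive frequency;
    ``weighted=False`` counts every unique clone once.  Skewness is the
    standardized third central moment and kurtosis is excess kurtosis, both
    with population (n) denominators.  With a single distinct length the
    variance is 0 and the shape moments are undefined (NaN).
    """
    if not dist.lengths:
        raise ValueError("empty length distribution")
    x = np.asarray(dist.lengths, dtype=float)
    w = np.asarray(dist.frequencies if weighted else dist.unique_counts, dtype=float)
    w = w / w.sum()
    mean = float(np.sum(w * x))
    var = float(np.sum(w * (x - mean) ** 2))
    if var == 0.0:
        log.warning("single distinct length %s: skewness/kurtosis undefined",
                    dist.lengths[0])
        return LengthSummary(mean=mean, variance=0.0, skewness=math.nan,
                             kurtosis=math.nan, weighted=weighted)
    sd = math.sqrt(var)
    skew = float(np.sum(w * ((x - mean) / sd) ** 3))
    kurt = float(np.sum(w * ((x - mean) / sd) ** 4)) - 3.0
    return LengthSummary(mean=mean, variance=var, skewness=skew,
                         kurtosis=kurt, weighted=weighted)


def cohort_length_table(cohort, scale: str = "nt") -> pd.DataFrame:
    """Tidy per-sample length table (sample_id, scale, length, frequency,
    unique_count)."""
    frames = []
    for rep in cohort.repertoires:
        dist = length_distribution(rep, scale=scale)
        df = dist.to_frame()
        df.insert(0, "scale", scale)
        df.insert(0, "sample_id", rep.sample_id)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
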