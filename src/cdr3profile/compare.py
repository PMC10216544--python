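"""Dunn's post-hoc rank test for multi-sample comparison.

Observations from all groups are pooled and mid-ranked; for each pair of
groups (a, b) the statistic is

    z_ab = (mean_rank_a - mean_rank_b)
           / sqrt((N(N+1)/12 - T) * (1/n_a + 1/n_b))

with the tie correction T = sum_t (t^3 - t) / (12 (N - 1)) over tied-value
run lengths t, and a two-sided p-value from the standard normal.  Without
ties T = 0 and the statistic reduces to the classical Kruskal–Wallis-based
form.  Multiplicity adjustment (Bonferroni or Holm) is optional; the
unadjusted p is the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .clonality import clone_frequencies
from .io import Cohort


@dataclass(frozen=True)
class PairwiseResult:
    sample_a: str
    sample_b: str
    z: float
    p: float
    p_adjusted: float


@dataclass
class GroupComparisonResult:
    pairs: list[PairwiseResult] = field(default_factory=list)
    adjustment: str = "none"

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame([
            {"sample_a": r.sample_a, "sample_b": r.sample_b, "z": r.z,
             "p": r.p, "p_adjusted": r.p_adjusted}
            for r in self.pairs
        ])


def dunns_test(
    samples: Sequence[tuple[str, Sequence[float]]],
    adjust: str = "none",
) -> GroupComparisonResult:
    """Pairwise Dunn's test over labelled observation groups."""
    if adjust not in ("none", "bonferroni", "holm"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    for label, obs in samples:
        if len(obs) == 0:
            raise ValueError(f"group {label!r} has no observations")

    pooled = np.concatenate([np.asarray(obs, dtype=float) for _, obs in samples])
    N = len(pooled)
    ranks = stats.rankdata(pooled)  # midranks for ties

    # tie correction over runs of equal values in the pooled sample
    _, tie_counts = np.unique(pooled, return_counts=True)
    T = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (N - 1))

    mean_ranks: dict[str, float] = {}
    sizes: dict[str, int] = {}
    start = 0
    for label, obs in samples:
        n = len(obs)
        mean_ranks[label] = float(ranks[start:start + n].mean())
        sizes[label] = n
        start += n

    base_var = N * (N + 1) / 12.0 - T
    labels = [label for label, _ in samples]
    raw: list[tuple[str, str, float, float]] = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            var = base_var * (1.0 / sizes[a] + 1.0 / sizes[b])
            if var <= 0.0:
                z = p = math.nan  # all pooled observations identical
            else:
                z = (mean_ranks[a] - mean_ranks[b]) / math.sqrt(var)
                p = 2.0 * stats.norm.sf(abs(z))
            raw.append((a, b, z, p))

    pvals = [p for _, _, _, p in raw]
    if adjust == "none" or all(math.isnan(p) for p in pvals):
        adjusted = pvals
    else:
        finite = [0.5 if math.isnan(p) else p for p in pvals]
        adjusted = list(multipletests(finite, method=adjust)[1])
        adjusted = [math.nan if math.isnan(p) else q
                    for p, q in zip(pvals, adjusted)]

    return GroupComparisonResult(
        pairs=[PairwiseResult(a, b, z, p, q)
               for (a, b, z, p), q in zip(raw, adjusted)],
        adjustment=adjust,
    )


def compare_clone_frequencies(
    cohort: Cohort, adjust: str = "none"
) -> GroupComparisonResult:
    """Pipeline preset: compare per-clone productive frequencies across
    samples.

    This operationalizes a between-sample comparison of clonal frequency
    distributions: each sample contributes its productive clone frequencies
    as the observation vector.  It is one reasonable reading of an
    under-specified analysis; the generic :func:`dunns_test` accepts any
    other observable.
    """
    samples = [
        (rep.sample_id, [p for _, p in clone_frequencies(rep)])
        for rep in cohort.repertoires
    ]
    return dunns_test(samples, adjust=adjust)
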