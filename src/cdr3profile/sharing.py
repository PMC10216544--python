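"""Cross-sample clone sharing and Clustal-style conservation annotation.

Sharing is exact string identity of productive CDR3 amino acid sequences
across samples (convergent recombination means distinct nucleotide
junctions can encode one peptide, so amino acid level is the default; a
nucleotide mode exists).  Equal-length shared sets are column-annotated
with the Clustal consensus symbols: '*' for a fully conserved column, ':'
when all residues fall in one strongly similar group (roughly Gonnet PAM
250 score > 0.5), '.' for one weakly similar group (score <= 0.5 and > 0),
and space otherwise.  Gapped multiple alignment of unequal-length sets is
delegated to an external aligner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .io import Cohort, Group
from .translate import productive

# Strong/weak similarity groups as published with Clustal X (Thompson et
# al. 1997); "roughly equivalent" to Gonnet PAM 250 thresholds 0.5 / 0.
CLUSTAL_STRONG: tuple[frozenset[str], ...] = tuple(
    frozenset(g) for g in
    ("STA", "NEQK", "NHQK", "NDEQ", "QHRK", "MILV", "MILF", "HY", "FYW")
)
CLUSTAL_WEAK: tuple[frozenset[str], ...] = tuple(
    frozenset(g) for g in
    ("CSA", "ATV", "SAG", "STNK", "STPA", "SGND", "SNDEQK", "NDEQHK",
     "NEQHRK", "FVLIM", "HFY")
)


@dataclass(frozen=True)
class ConservationScheme:
    strong: tuple[frozenset[str], ...] = CLUSTAL_STRONG
    weak: tuple[frozenset[str], ...] = CLUSTAL_WEAK


DEFAULT_SCHEME = ConservationScheme()


@dataclass
class SharedCloneReport:
    """Shared sequences with the sample sets carrying them."""

    entries: list[tuple[str, frozenset[str]]] = field(default_factory=list)
    within_group: int = 0
    between_group: int = 0

    def to_frame(self, cohort: Cohort | None = None) -> pd.DataFrame:
        rows = []
        for seq, samples in self.entries:
            row = {"cdr3_aa": seq, "samples": ",".join(sorted(samples))}
            if cohort is not None:
                row["groups"] = ",".join(sorted(
                    {cohort[s].group.value for s in samples}
                ))
            rows.append(row)
        return pd.DataFrame(rows)


def shared_clones(cohort: Cohort, level: str = "aa") -> SharedCloneReport:
    """Find sequences present in at least two samples.

    ``level='aa'`` (default) matches productive amino acid sequences;
    ``level='nt'`` matches nucleotide junctions.  The summary counts split
    shared sequences into within-group (all carriers share a group label)
    and between-group.
    """
    if level not in ("aa", "nt"):
        raise ValueError(f"level must be 'aa' or 'nt', got {level!r}")
    carriers: dict[str, set[str]] = {}
    for rep in cohort.repertoires:
        for r in productive(rep):
            key = r.cdr3_aa if level == "aa" else r.cdr3_nt
            carriers.setdefault(key, set()).add(rep.sample_id)
    entries = sorted(
        (seq, frozenset(samples))
        for seq, samples in carriers.items() if len(samples) >= 2
    )
    within = between = 0
    for _, samples in entries:
        groups = {cohort[s].group for s in samples}
        if len(groups) == 1 and Group.UNLABELED not in groups:
            within += 1
        else:
            between += 1
    return SharedCloneReport(entries=entries, within_group=within,
                             between_group=between)


def conservation_string(
    sequences: Sequence[str],
    scheme: ConservationScheme = DEFAULT_SCHEME,
) -> str:
    """Clustal consensus symbol line for a gapless equal-length set."""
    seqs = [s.upper() for s in sequences]
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError(
            "sequences differ in length; align them with an external MSA "
            "tool (e.g. Clustal Omega or MAFFT) before annotation"
        )
    symbols = []
    for col in zip(*seqs):
        residues = frozenset(col)
        if len(residues) == 1:
            symbols.append("*")
        elif any(residues <= g for g in scheme.strong):
            symbols.append(":")
        elif any(residues <= g for g in scheme.weak):
            symbols.append(".")
        else:
            symbols.append(" ")
    return "".join(symbols)


def format_alignment_block(
    labelled: Sequence[tuple[str, str]],
    scheme: ConservationScheme = DEFAULT_SCHEME,
) -> str:
    """Clustal-style text block: labelled sequences plus the symbol line."""
    width = max(len(label) for label, _ in labelled) + 2
    lines = [f"{label:<{width}}{seq}" for label, seq in labelled]
    lines.append(" " * width + conservation_string([s for _, s in labelled], scheme))
    return "\n".join(lines) + "\n"
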