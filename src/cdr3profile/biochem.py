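"""Peptide isoelectric points and residue-property composition.

The theoretical isoelectric point (pI) is the pH at which the
Henderson–Hasselbalch net charge of the peptide's ionizable groups — the
termini plus K, R, H (basic) and D, E, C, Y (acidic) side chains — crosses
zero.  Net charge is strictly decreasing in pH, so the root is unique and
bisection on [0, 14] finds it deterministically.

Residue composition tallies occurrences of eight IUPAC-IUB property groups
(Aliphatic, Aromatic, Sulphur, Basic, Acidic, Aliphatic hydroxyl, and the
two aminoacyl-tRNA-synthetase classes).  The groups overlap, so one residue
may count toward several; the two synthetase classes partition the residue
alphabet, so their percentages always sum to 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Default pKa constants for the nine ionizable groups.  A widely used
#: published set; override with any tool's constants via ``load_pka`` to
#: match that tool's pI values.
DEFAULT_PKA: dict[str, float] = {
    "N_terminus": 8.6,
    "C_terminus": 3.6,
    "K": 10.8,
    "R": 12.5,
    "H": 6.5,
    "D": 3.9,
    "E": 4.1,
    "C": 8.5,
    "Y": 10.1,
}

_BASIC_SIDE = ("K", "R", "H")
_ACIDIC_SIDE = ("D", "E", "C", "Y")


def load_pka(path: str | Path) -> dict[str, float]:
    """Read a two-column key-value pKa config (group<TAB>pKa)."""
    table = dict(DEFAULT_PKA)
    df = pd.read_csv(path, sep="\t", comment="#", names=["group", "pka"],
                     header=None, dtype={"group": str})
    for _, row in df.iterrows():
        key = str(row["group"]).strip()
        if key not in DEFAULT_PKA:
            raise ValueError(f"unknown ionizable group {key!r} in {path}")
        table[key] = float(row["pka"])
    validate_pka(table)
    return table


def validate_pka(pka: Mapping[str, float]) -> None:
    missing = set(DEFAULT_PKA) - set(pka)
    if missing:
        raise ValueError(f"pKa table is missing groups {sorted(missing)}")
    for key, val in pka.items():
        if not 0.0 < float(val) < 14.0:
            raise ValueError(f"pKa for {key} out of (0, 14): {val}")


def _check_standard(cdr3_aa: str) -> str:
    if not cdr3_aa:
        raise ValueError("empty peptide")
    seq = cdr3_aa.upper()
    for res in seq:
        if res not in STANDARD_RESIDUES:
            raise ValueError(
                f"residue {res!r} has no defined pKa; only the 20 standard "
                "amino acids are supported here"
            )
    return seq


def net_charge(cdr3_aa: str, pH: float, pka: Mapping[str, float] | None = None) -> float:
    """Henderson–Hasselbalch net charge of the peptide at the given pH."""
    pka = DEFAULT_PKA if pka is None else pka
    seq = _check_standard(cdr3_aa)
    pos = 1.0 / (1.0 + 10.0 ** (pH - pka["N_terminus"]))
    neg = 1.0 / (1.0 + 10.0 ** (pka["C_terminus"] - pH))
    for res in _BASIC_SIDE:
        n = seq.count(res)
        if n:
            pos += n / (1.0 + 10.0 ** (pH - pka[res]))
    for res in _ACIDIC_SIDE:
        n = seq.count(res)
        if n:
            neg += n / (1.0 + 10.0 ** (pka[res] - pH))
    return pos - neg


@dataclass(frozen=True)
class IsoelectricResult:
    cdr3_aa: str
    pI: float


def isoelectric_point(
    cdr3_aa: str,
    pka: Mapping[str, float] | None = None,
    tol: float = 1e-4,
) -> IsoelectricResult:
    """Theoretical pI by bisection of the net-charge curve on [0, 14].

    Stops when |charge| < ``tol`` (charge units) or the bracketing interval
    is narrower than 1e-6 pH.  Monotonicity of the charge in pH makes the
    result deterministic and unique.
    """
    lo, hi = 0.0, 14.0
    mid = 7.0
    while hi - lo > 1e-6:
        mid = 0.5 * (lo + hi)
        q = net_charge(cdr3_aa, mid, pka)
        # the charge curve can be nearly flat around the root, so the
        # charge tolerance alone does not pin down the pH; require the
        # bracket to be tight as well before stopping early
        if abs(q) < tol and hi - lo < 1e-3:
            break
        if q > 0:
            lo = mid
        else:
            hi = mid
    return IsoelectricResult(cdr3_aa=cdr3_aa.upper(), pI=mid)


# --- residue-property composition -----------------------------------------

#: Ordered property scheme.  B (Asx) and Z (Glx) appear in the published
#: group definitions and are accepted in composition counting, though the
#: standard genetic code never produces them.
DEFAULT_SCHEME: tuple[tuple[str, frozenset[str]], ...] = (
    ("Aliphatic", frozenset("GAVLI")),
    ("Aromatic", frozenset("FWY")),
    ("Sulphur", frozenset("CM")),
    ("Basic", frozenset("KRH")),
    ("Acidic", frozenset("BDENQZ")),
    ("Aliphatic hydroxyl", frozenset("ST")),
    ("tRNA synthetase class I", frozenset("ZEQRCMVILYW")),
    ("tRNA synthetase class II", frozenset("BGAPSTHDNKF")),
)

_COMPOSITION_ALPHABET = STANDARD_RESIDUES | {"B", "Z"}


@dataclass
class CompositionTable:
    """Times-found counts and percentages per property group."""

    counts: dict[str, int]
    total_residues: int

    @property
    def percentages(self) -> dict[str, float]:
        if self.total_residues == 0:
            return {g: 0.0 for g in self.counts}
        return {g: 100.0 * c / self.total_residues for g, c in self.counts.items()}

    @classmethod
    def from_counts(cls, counts: Mapping[str, int], total_residues: int | None = None
                    ) -> "CompositionTable":
        """Build a table from precomputed times-found counts.

        When ``total_residues`` is omitted it is taken as the sum of the two
        synthetase-class counts, which together cover every residue exactly
        once.
        """
        if total_residues is None:
            total_residues = (counts["tRNA synthetase class I"]
                              + counts["tRNA synthetase class II"])
        return cls(counts=dict(counts), total_residues=total_residues)

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages
        return pd.DataFrame({
            "group": list(self.counts),
            "times_found": list(self.counts.values()),
            "percentage": [pct[g] for g in self.counts],
        })


def residue_composition(
    peptides: Iterable[str],
    scheme: tuple[tuple[str, frozenset[str]], ...] = DEFAULT_SCHEME,
    weights: Iterable[int] | None = None,
) -> CompositionTable:
    """Tally property-group occurrences across a peptide collection.

    Each residue may count toward several overlapping groups; percentages
    are on the total residue count.  ``weights`` (e.g. template counts)
    multiply each peptide's contribution; the default counts every unique
    peptide once, matching raw times-found bookkeeping.
    """
    peptides = list(peptides)
    if not peptides:
        raise ValueError("empty peptide collection")
    wts = [1] * len(peptides) if weights is None else list(weights)
    if len(wts) != len(peptides):
        raise ValueError("weights length must match peptides length")
    counts = {name: 0 for name, _ in scheme}
    total = 0
    for pep, w in zip(peptides, wts):
        seq = pep.upper()
        for res in seq:
            if res not in _COMPOSITION_ALPHABET:
                raise ValueError(f"unknown residue {res!r} in {pep!r}")
        total += w * len(seq)
        for name, members in scheme:
            counts[name] += w * sum(1 for res in seq if res in members)
    return CompositionTable(counts=counts, total_residues=total)
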