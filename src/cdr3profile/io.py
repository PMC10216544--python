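"""Reading and writing TCR-beta rearrangement tables and CDR3 FASTA files.

Two tab-separated dialects are understood:

* an immunoSEQ-export-like dialect with columns ``rearrangement``,
  ``amino_acid``, ``templates``, ``frame_type`` (In/Out/Stop) and
  ``sample_name``;
* the AIRR Rearrangement subset with ``junction``, ``junction_aa``,
  ``duplicate_count``, ``productive`` (plus, when present, ``vj_in_frame``
  and ``stop_codon``) and ``repertoire_id``.

Both map onto the same in-memory model: :class:`Rearrangement` rows grouped
into per-sample :class:`Repertoire` objects inside a :class:`Cohort`.
Duplicate nucleotide junctions within a sample are merged by summing their
template counts, so template totals are conserved by de-duplication.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

_VALID_NT = frozenset("ACGT")


class FormatError(ValueError):
    """A rearrangement table does not conform to a supported dialect."""


class FrameStatus(str, Enum):
    IN_FRAME = "in_frame"
    OUT_OF_FRAME = "out_of_frame"
    STOP = "stop"


class Group(str, Enum):
    ARDS = "ARDS"
    NON_ARDS = "non_ARDS"
    UNLABELED = "unlabeled"


@dataclass
class Rearrangement:
    """One unique CDR3 nucleotide junction with its template abundance.

    ``templates`` is the number of input DNA molecules attributed to the
    clonotype — the abundance unit every downstream frequency uses.
    ``productive`` is filled in by :func:`cdr3profile.translate.classify_productive`.
    """

    cdr3_nt: str
    templates: int = 1
    cdr3_aa: str | None = None
    frame_status: FrameStatus | None = None
    sample_id: str = ""
    productive: bool | None = None

    def __post_init__(self) -> None:
        if not self.cdr3_nt:
            raise ValueError("cdr3_nt must be nonempty")
        self.cdr3_nt = self.cdr3_nt.upper()
        bad = set(self.cdr3_nt) - _VALID_NT
        if bad:
            raise ValueError(
                f"non-ACGT character(s) {sorted(bad)} in cdr3_nt {self.cdr3_nt!r}"
            )
        if self.templates < 0:
            raise ValueError("templates must be >= 0")
        if self.frame_status is FrameStatus.IN_FRAME and len(self.cdr3_nt) % 3:
            raise ValueError(
                f"frame_status=in_frame but junction length {len(self.cdr3_nt)} "
                "is not a multiple of 3"
            )
        if self.cdr3_aa is not None:
            self.cdr3_aa = self.cdr3_aa.upper()


@dataclass
class Repertoire:
    """A sample's de-duplicated rearrangement set plus its clinical group."""

    sample_id: str
    group: Group = Group.UNLABELED
    rearrangements: list[Rearrangement] = field(default_factory=list)

    @classmethod
    def from_rearrangements(
        cls, sample_id: str, rows: Iterable[Rearrangement], group: Group = Group.UNLABELED
    ) -> "Repertoire":
        """Build a repertoire, merging duplicate nucleotide junctions.

        Template counts of duplicates are summed; first-seen order and
        first-seen annotations are kept.
        """
        merged: dict[str, Rearrangement] = {}
        for r in rows:
            prev = merged.get(r.cdr3_nt)
            if prev is None:
                merged[r.cdr3_nt] = Rearrangement(
                    cdr3_nt=r.cdr3_nt,
                    templates=r.templates,
                    cdr3_aa=r.cdr3_aa,
                    frame_status=r.frame_status,
                    sample_id=sample_id,
                )
            else:
                prev.templates += r.templates
                if prev.frame_status != r.frame_status:
                    log.warning(
                        "sample %s: duplicate junction %s has conflicting frame "
                        "annotations (%s vs %s); keeping the first",
                        sample_id, r.cdr3_nt, prev.frame_status, r.frame_status,
                    )
        return cls(sample_id=sample_id, group=group, rearrangements=list(merged.values()))

    def __len__(self) -> int:
        return len(self.rearrangements)

    @property
    def total_templates(self) -> int:
        return sum(r.templates for r in self.rearrangements)


@dataclass
class Cohort:
    repertoires: list[Repertoire]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.repertoires:
            raise ValueError("a cohort needs at least one repertoire")
        ids = [r.sample_id for r in self.repertoires]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate sample_id in cohort: {ids}")

    def __getitem__(self, sample_id: str) -> Repertoire:
        for rep in self.repertoires:
            if rep.sample_id == sample_id:
                return rep
        raise KeyError(sample_id)

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.repertoires]


# dialect -> {canonical field: accepted column names, in priority order}
_DIALECTS: dict[str, dict[str, tuple[str, ...]]] = {
    "immunoseq": {
        "cdr3_nt": ("rearrangement",),
        "cdr3_aa": ("amino_acid",),
        "templates": ("templates",),
        "frame": ("frame_type",),
        "sample_id": ("sample_name", "sample_id"),
    },
    "airr": {
        "cdr3_nt": ("junction",),
        "cdr3_aa": ("junction_aa",),
        "templates": ("duplicate_count",),
        "frame": ("productive",),
        "sample_id": ("repertoire_id", "sample_id"),
    },
}


def _detect_dialect(columns: list[str]) -> str:
    if "junction" in columns:
        return "airr"
    if "rearrangement" in columns:
        return "immunoseq"
    raise FormatError(
        "cannot detect dialect: expected a 'junction' (AIRR) or "
        f"'rearrangement' (immunoSEQ-like) column, got {columns}"
    )


def _frame_status_immunoseq(value: str) -> FrameStatus:
    v = str(value).strip().lower()
    if v.startswith("in"):
        return FrameStatus.IN_FRAME
    if v.startswith("out"):
        return FrameStatus.OUT_OF_FRAME
    if v.startswith("stop"):
        return FrameStatus.STOP
    raise ValueError(f"unrecognized frame_type value {value!r}")


_TRUTHY = {"t", "true", "1", "yes"}
_FALSY = {"f", "false", "0", "no"}


def _parse_bool(value) -> bool | None:
    v = str(value).strip().lower()
    if v in _TRUTHY:
        return True
    if v in _FALSY:
        return False
    return None


def _frame_status_airr(row: pd.Series, nt: str) -> FrameStatus | None:
    if "stop_codon" in row.index and _parse_bool(row["stop_codon"]) is True:
        return FrameStatus.STOP
    if "vj_in_frame" in row.index and _parse_bool(row["vj_in_frame"]) is False:
        return FrameStatus.OUT_OF_FRAME
    productive = _parse_bool(row.get("productive"))
    if productive is True:
        return FrameStatus.IN_FRAME
    if productive is False:
        # non-productive: a frameshifted junction if the length breaks the
        # frame, otherwise an in-frame junction carrying a stop codon
        return FrameStatus.OUT_OF_FRAME if len(nt) % 3 else FrameStatus.STOP
    return None


def read_metadata(path: str | Path) -> dict[str, Group]:
    """Read a two-column (sample_id, group) TSV into a label map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise FormatError(f"metadata file is missing mandatory column '{col}'")
    out: dict[str, Group] = {}
    for _, row in df.iterrows():
        label = row["group"].strip()
        try:
            out[row["sample_id"].strip()] = Group(label)
        except ValueError as exc:
            raise FormatError(
                f"unknown group label {label!r}; expected one of "
                f"{[g.value for g in Group]}"
            ) from exc
    return out


def read_rearrangements(
    path: str | Path,
    dialect: str = "auto",
    metadata: str | Path | Mapping[str, Group] | None = None,
) -> Cohort:
    """Read a rearrangement TSV (either dialect) into a :class:`Cohort`.

    Rows sharing a nucleotide junction within a sample are merged with
    summed template counts.  Group labels come from ``metadata`` (a path to
    a two-column TSV or an in-memory mapping); they are never inferred from
    sample names.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str).dropna(how="all")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty rearrangement file") from exc
    if df.empty:
        raise FormatError(f"{path}: rearrangement file has a header but no rows")
    df.columns = [c.strip().lower() for c in df.columns]

    if dialect == "auto":
        dialect = _detect_dialect(list(df.columns))
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    cols = _DIALECTS[dialect]

    def find(fieldname: str) -> str | None:
        for cand in cols[fieldname]:
            if cand in df.columns:
                return cand
        return None

    nt_col = find("cdr3_nt")
    if nt_col is None:
        raise FormatError(
            f"{path}: missing mandatory column '{cols['cdr3_nt'][0]}' for "
            f"dialect '{dialect}'"
        )
    aa_col = find("cdr3_aa")
    tmpl_col = find("templates")
    frame_col = find("frame")
    sample_col = find("sample_id")
    if tmpl_col is None:
        log.warning(
            "%s: no template-count column; assuming 1 template per row "
            "(clone frequencies will be unweighted)", path,
        )
    if sample_col is None:
        log.warning("%s: no sample column; treating the whole file as sample %r",
                    path, path.stem)

    groups: Mapping[str, Group] = {}
    if metadata is not None:
        groups = metadata if isinstance(metadata, Mapping) else read_metadata(metadata)

    rows_by_sample: dict[str, list[Rearrangement]] = {}
    for idx, row in df.iterrows():
        nt = str(row[nt_col]).strip()
        try:
            frame = None
            if frame_col is not None and not pd.isna(row[frame_col]):
                if dialect == "immunoseq":
                    frame = _frame_status_immunoseq(row[frame_col])
                else:
                    frame = _frame_status_airr(row, nt.upper())
            aa = None
            if aa_col is not None and not pd.isna(row[aa_col]) and str(row[aa_col]).strip():
                aa = str(row[aa_col]).strip()
            templates = 1 if tmpl_col is None else int(float(row[tmpl_col]))
            sample_id = (
                str(row[sample_col]).strip() if sample_col is not None else path.stem
            )
            rec = Rearrangement(
                cdr3_nt=nt, templates=templates, cdr3_aa=aa,
                frame_status=frame, sample_id=sample_id,
            )
        except ValueError as exc:
            raise FormatError(f"{path}: row {idx}: {exc}") from exc
        rows_by_sample.setdefault(sample_id, []).append(rec)

    repertoires = [
        Repertoire.from_rearrangements(
            sid, rows, group=groups.get(sid, Group.UNLABELED)
        )
        for sid, rows in rows_by_sample.items()
    ]
    return Cohort(repertoires=repertoires, provenance=f"read from {path} ({dialect})")


def write_rearrangements(
    cohort: Cohort, path: str | Path, dialect: str = "immunoseq"
) -> None:
    """Write a cohort back out as a dialect-valid rearrangement TSV."""
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    rows = []
    for rep in cohort.repertoires:
        for r in rep.rearrangements:
            if dialect == "immunoseq":
                frame = {
                    FrameStatus.IN_FRAME: "In",
                    FrameStatus.OUT_OF_FRAME: "Out",
                    FrameStatus.STOP: "Stop",
                    None: "",
                }[r.frame_status]
                rows.append({
                    "rearrangement": r.cdr3_nt,
                    "amino_acid": r.cdr3_aa or "",
                    "templates": r.templates,
                    "frame_type": frame,
                    "sample_name": rep.sample_id,
                })
            else:
                rows.append({
                    "junction": r.cdr3_nt,
                    "junction_aa": r.cdr3_aa or "",
                    "duplicate_count": r.templates,
                    "productive": "T" if r.frame_status is FrameStatus.IN_FRAME else "F",
                    "vj_in_frame": "F" if r.frame_status is FrameStatus.OUT_OF_FRAME else "T",
                    "stop_codon": "T" if r.frame_status is FrameStatus.STOP else "F",
                    "repertoire_id": rep.sample_id,
                })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_metadata(cohort: Cohort, path: str | Path) -> None:
    pd.DataFrame(
        [{"sample_id": rep.sample_id, "group": rep.group.value}
         for rep in cohort.repertoires]
    ).to_csv(path, sep="\t", index=False)


def write_fasta(repertoire: Repertoire, path: str | Path, width: int = 80) -> int:
    """Write the repertoire's CDR3 amino acid sequences as FASTA.

    Headers are ``sample_id|index|templates``.  Returns the number of
    records written.  Every record must already carry a translation.
    """
    n = 0
    with open(path, "w") as fh:
        for i, r in enumerate(repertoire.rearrangements):
            if r.cdr3_aa is None:
                raise ValueError(
                    f"record {i} of sample {repertoire.sample_id} has no "
                    "cdr3_aa; run cdr3profile.translate.translate_repertoire first"
                )
            fh.write(f">{repertoire.sample_id}|{i}|{r.templates}\n")
            for j in range(0, len(r.cdr3_aa), width):
                fh.write(r.cdr3_aa[j:j + width] + "\n")
            n += 1
    return n


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file back as (header, sequence) pairs, in file order."""
    return [(rec.description, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
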