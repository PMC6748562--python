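"""Reading, writing and filtering reference libraries and query sets.

A reference library is a FASTA file of COI sequences plus a TSV of
per-record metadata (taxonomic lineage, BIN label, public flag, deposit
year, provenance countries).  Queries are a FASTA plus a TSV of specimen
metadata; a specimen absent from the FASTA simply has no sequence
(sequencing failure).  Two library *views* mirror the BOLD search options:

* ``SLBR`` — species-level barcode records: species-named or interim
  (BIN-labelled) records of at least 500 bp, public or not;
* ``PRBD`` — public record barcode database: published records of at least
  500 bp, regardless of identification rank.

A *snapshot* applies a view plus a deposit-year cutoff, reconstructing what
the library looked like in a given calendar year.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._align import IUPAC_CHARS, AlphabetError
from .taxonomy import RANKS, Rank, TaxonLineage

__all__ = [
    "ReferenceRecord",
    "QuerySpecimen",
    "LibraryView",
    "SLBR",
    "PRBD",
    "LibraryIOError",
    "read_library",
    "write_library",
    "read_queries",
    "write_queries",
    "snapshot",
    "LIBRARY_COLUMNS",
    "QUERY_COLUMNS",
]

LIBRARY_COLUMNS = (
    "record_id",
    "order",
    "superfamily",
    "family",
    "subfamily",
    "genus",
    "species",
    "bin_label",
    "is_public",
    "year_added",
    "country_of_origin",
    "country_of_interception",
    "capture_exception",
)

QUERY_COLUMNS = (
    "specimen_id",
    "order",
    "superfamily",
    "family",
    "subfamily",
    "genus",
    "species",
    "life_stage",
    "country_of_origin",
    "country_of_interception",
)

LIFE_STAGES = ("larva", "pupa", "adult", "unknown")

_MIN_YEAR = 1990


class LibraryIOError(ValueError):
    """Raised for cross-file inconsistencies or malformed metadata."""


def _check_alphabet(seq: str, owner: str) -> None:
    bad = sorted({c for c in seq if c != "-" and c not in IUPAC_CHARS})
    if bad:
        raise AlphabetError(f"{owner}: non-IUPAC characters {bad!r}")
    if not seq.replace("-", ""):
        raise AlphabetError(f"{owner}: sequence is empty")


@dataclass(frozen=True)
class ReferenceRecord:
    """One reference-library barcode record."""

    record_id: str
    sequence: str
    lineage: TaxonLineage
    bin_label: Optional[str] = None
    is_public: bool = False
    year_added: int = _MIN_YEAR
    country_of_origin: Optional[str] = None
    country_of_interception: Optional[str] = None
    capture_exception: bool = False

    def __post_init__(self) -> None:
        _check_alphabet(self.sequence, f"record {self.record_id!r}")
        if self.year_added < _MIN_YEAR:
            raise LibraryIOError(
                f"record {self.record_id!r}: year_added {self.year_added} < {_MIN_YEAR}"
            )

    @property
    def seq_length(self) -> int:
        """Sequence length in bp, counting every non-gap character (incl. N)."""
        return len(self.sequence) - self.sequence.count("-")


@dataclass(frozen=True)
class QuerySpecimen:
    """An intercepted specimen: morphology-based lineage, maybe a sequence."""

    specimen_id: str
    morph_lineage: TaxonLineage
    sequence: Optional[str] = None
    life_stage: str = "unknown"
    country_of_origin: Optional[str] = None
    country_of_interception: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sequence is not None:
            _check_alphabet(self.sequence, f"specimen {self.specimen_id!r}")
        if self.life_stage not in LIFE_STAGES:
            raise LibraryIOError(
                f"specimen {self.specimen_id!r}: life_stage {self.life_stage!r} "
                f"not in {LIFE_STAGES}"
            )
        if self.morph_lineage.is_interim_only():
            raise LibraryIOError(
                f"specimen {self.specimen_id!r}: morphological lineage needs a Linnaean name"
            )

    @property
    def has_sequence(self) -> bool:
        return self.sequence is not None


@dataclass(frozen=True)
class LibraryView:
    """A named library filter with its minimum barcode length."""

    name: str
    min_length_bp: int = 500

    def __post_init__(self) -> None:
        if self.name not in ("SLBR", "PRBD"):
            raise LibraryIOError(f"unknown library view {self.name!r}")
        if self.min_length_bp <= 0:
            raise LibraryIOError("min_length_bp must be positive")

    def admits(self, record: ReferenceRecord) -> bool:
        if record.seq_length < self.min_length_bp:
            return False
        if self.name == "PRBD":
            return record.is_public
        # SLBR: species-level identification, interim taxonomy included
        return (
            record.lineage.name_at(Rank.SPECIES) is not None
            or record.lineage.interim_label is not None
            or record.bin_label is not None
        )


SLBR = LibraryView("SLBR")
PRBD = LibraryView("PRBD")


def snapshot(
    records: Sequence[ReferenceRecord], year: int, view: LibraryView
) -> list[ReferenceRecord]:
    """Records deposited by ``year`` that the view admits.

    Monotone: ``snapshot(y1) ⊆ snapshot(y2)`` for ``y1 <= y2`` under the
    same view.
    """
    return [r for r in records if r.year_added <= year and view.admits(r)]


# ---------------------------------------------------------------------------
# TSV / FASTA plumbing


def _lineage_from_row(row: pd.Series, owner: str, errors: list[str]) -> Optional[TaxonLineage]:
    names = {}
    for rank in RANKS:
        value = str(row.get(rank.label, "") or "").strip()
        if value:
            names[rank] = value
    interim = str(row.get("bin_label", "") or "").strip() or None
    try:
        return TaxonLineage(names=names, interim_label=interim)
    except Exception as exc:
        errors.append(f"{owner}: {exc}")
        return None


def _parse_bool(value: str, owner: str, column: str, errors: list[str]) -> bool:
    v = str(value).strip().lower()
    if v in ("1", "true", "t", "yes"):
        return True
    if v in ("0", "false", "f", "no", ""):
        return False
    errors.append(f"{owner}: cannot parse {column}={value!r} as boolean")
    return False


def _read_tsv(path, key_column: str, columns: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise LibraryIOError(f"{path}: missing TSV columns {missing}")
    dup = df[key_column][df[key_column].duplicated()].tolist()
    if dup:
        raise LibraryIOError(f"{path}: duplicate {key_column} values {sorted(set(dup))}")
    return df


def _read_fasta(path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise LibraryIOError(f"{path}: duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    return seqs


def read_library(fasta_path, metadata_path) -> list[ReferenceRecord]:
    """Load and validate a reference library from FASTA + metadata TSV.

    Every FASTA record must have a metadata row and vice versa; mismatched
    or malformed entries are collected and raised together.
    """
    seqs = _read_fasta(fasta_path)
    meta = _read_tsv(metadata_path, "record_id", LIBRARY_COLUMNS)
    errors: list[str] = []
    meta_ids = set(meta["record_id"])
    for rid in sorted(set(seqs) - meta_ids):
        errors.append(f"record {rid!r}: sequence present but no metadata row")
    for rid in sorted(meta_ids - set(seqs)):
        errors.append(f"record {rid!r}: metadata row present but no sequence")

    records: list[ReferenceRecord] = []
    for _, row in meta.iterrows():
        rid = row["record_id"]
        if rid not in seqs:
            continue
        owner = f"record {rid!r}"
        lineage = _lineage_from_row(row, owner, errors)
        if lineage is None:
            continue
        try:
            year = int(row["year_added"])
        except ValueError:
            errors.append(f"{owner}: year_added {row['year_added']!r} is not an integer")
            continue
        try:
            records.append(
                ReferenceRecord(
                    record_id=rid,
                    sequence=seqs[rid],
                    lineage=lineage,
                    bin_label=str(row["bin_label"]).strip() or None,
                    is_public=_parse_bool(row["is_public"], owner, "is_public", errors),
                    year_added=year,
                    country_of_origin=str(row["country_of_origin"]).strip() or None,
                    country_of_interception=str(row["country_of_interception"]).strip() or None,
                    capture_exception=_parse_bool(
                        row["capture_exception"], owner, "capture_exception", errors
                    ),
                )
            )
        except (AlphabetError, LibraryIOError) as exc:
            errors.append(str(exc))
    if errors:
        raise LibraryIOError("invalid reference library:\n  " + "\n  ".join(errors))
    return records


def write_library(records: Iterable[ReferenceRecord], fasta_path, metadata_path) -> None:
    """Emit a library in the same FASTA + TSV dialect that ``read_library`` reads."""
    records = list(records)
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.record_id, description="") for r in records),
        str(fasta_path),
        "fasta",
    )
    rows = []
    for r in records:
        row = {"record_id": r.record_id}
        for rank in RANKS:
            row[rank.label] = r.lineage.name_at(rank) or ""
        row.update(
            bin_label=r.bin_label or "",
            is_public=str(r.is_public).lower(),
            year_added=r.year_added,
            country_of_origin=r.country_of_origin or "",
            country_of_interception=r.country_of_interception or "",
            capture_exception=str(r.capture_exception).lower(),
        )
        rows.append(row)
    pd.DataFrame(rows, columns=list(LIBRARY_COLUMNS)).to_csv(
        metadata_path, sep="\t", index=False
    )


def read_queries(fasta_path, metadata_path) -> list[QuerySpecimen]:
    """Load query specimens; specimens missing from the FASTA have no sequence."""
    seqs = _read_fasta(fasta_path) if fasta_path is not None else {}
    meta = _read_tsv(metadata_path, "specimen_id", QUERY_COLUMNS)
    errors: list[str] = []
    meta_ids = set(meta["specimen_id"])
    for sid in sorted(set(seqs) - meta_ids):
        errors.append(f"specimen {sid!r}: sequence present but no metadata row")

    specimens: list[QuerySpecimen] = []
    for _, row in meta.iterrows():
        sid = row["specimen_id"]
        owner = f"specimen {sid!r}"
        names = {
            rank: str(row.get(rank.label, "") or "").strip()
            for rank in RANKS
            if str(row.get(rank.label, "") or "").strip()
        }
        try:
            lineage = TaxonLineage(names=names)
        except Exception as exc:
            errors.append(f"{owner}: {exc}")
            continue
        stage = str(row["life_stage"]).strip().lower() or "unknown"
        try:
            specimens.append(
                QuerySpecimen(
                    specimen_id=sid,
                    morph_lineage=lineage,
                    sequence=seqs.get(sid),
                    life_stage=stage,
                    country_of_origin=str(row["country_of_origin"]).strip() or None,
                    country_of_interception=str(row["country_of_interception"]).strip() or None,
                )
            )
        except (AlphabetError, LibraryIOError) as exc:
            errors.append(str(exc))
    if errors:
        raise LibraryIOError("invalid query set:\n  " + "\n  ".join(errors))
    return specimens


def write_queries(specimens: Iterable[QuerySpecimen], fasta_path, metadata_path) -> None:
    specimens = list(specimens)
    SeqIO.write(
        (
            SeqRecord(Seq(s.sequence), id=s.specimen_id, description="")
            for s in specimens
            if s.sequence is not None
        ),
        str(fasta_path),
        "fasta",
    )
    rows = []
    for s in specimens:
        row = {"specimen_id": s.specimen_id}
        for rank in RANKS:
            row[rank.label] = s.morph_lineage.name_at(rank) or ""
        row.update(
            life_stage=s.life_stage,
            country_of_origin=s.country_of_origin or "",
            country_of_interception=s.country_of_interception or "",
        )
        rows.append(row)
    pd.DataFrame(rows, columns=list(QUERY_COLUMNS)).to_csv(metadata_path, sep="\t", index=False)
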