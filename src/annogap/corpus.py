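"""Corpus model: taxonomic ranks, lineages, sequence records and FASTA/TSV I/O.

A corpus is a FASTA file of DNA sequences plus a tab-separated metadata table
keyed by accession.  The metadata dialect is fixed: columns
``accession, release_date, lineage, country, journal, study_id`` with a header
row, UTF-8, ISO-8601 dates and a semicolon-delimited seven-rank lineage.
"""

from __future__ import annotations

import datetime as dt
import enum
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "Rank",
    "RANKS",
    "Lineage",
    "SequenceRecord",
    "CorpusError",
    "parse_lineage",
    "annotation_depth",
    "is_fully_identified",
    "read_corpus",
    "write_corpus",
    "METADATA_COLUMNS",
]

METADATA_COLUMNS = ("accession", "release_date", "lineage", "country", "journal", "study_id")

#: IUPAC nucleotide one-letter codes (unambiguous + ambiguity + U), upper case.
IUPAC_NUCLEOTIDES = frozenset("ACGTURYSWKMBDHVN")

#: Tokens that denote an unidentified name at a rank (compared case-insensitively).
DEFAULT_PLACEHOLDER_TOKENS = frozenset({"", "unidentified", "sp.", "incertae sedis"})

#: Species epithets matching this pattern are provisional, not full binomials.
DEFAULT_PROVISIONAL_PATTERN = re.compile(r"(\ssp\.$)|(uncultured)", re.IGNORECASE)


class CorpusError(ValueError):
    """Raised on malformed corpus input (bad dates, accessions, sequences...)."""


class Rank(enum.IntEnum):
    """The seven canonical taxonomic ranks, ordered shallow to deep."""

    KINGDOM = 0
    PHYLUM = 1
    CLASS = 2
    ORDER = 3
    FAMILY = 4
    GENUS = 5
    SPECIES = 6

    @property
    def label(self) -> str:
        return self.name.lower()


RANKS: tuple[Rank, ...] = tuple(Rank)


@dataclass(frozen=True)
class Lineage:
    """Ordered seven-rank annotation; ``None`` marks an unidentified rank.

    Gaps are allowed: a rank may be unidentified while a deeper rank carries a
    name (e.g. a genus known without a settled family placement).
    """

    names: tuple[Optional[str], ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(RANKS):
            raise CorpusError(f"lineage must have {len(RANKS)} slots, got {len(self.names)}")
        for name in self.names:
            if name is not None and (not name or name != name.strip()):
                raise CorpusError(f"identified name must be non-empty and stripped: {name!r}")

    def name_at(self, rank: Rank) -> Optional[str]:
        return self.names[rank]

    def is_identified(self, rank: Rank) -> bool:
        return self.names[rank] is not None

    def identified_ranks(self) -> tuple[Rank, ...]:
        return tuple(r for r in RANKS if self.names[r] is not None)

    def depth(self) -> Optional[Rank]:
        """Deepest identified rank, or None for a fully unidentified lineage."""
        deepest = None
        for r in RANKS:
            if self.names[r] is not None:
                deepest = r
        return deepest

    def is_kingdom_level(self) -> bool:
        return self.depth() == Rank.KINGDOM

    def truncated(self, depth: Rank) -> "Lineage":
        """Copy with every rank deeper than ``depth`` set to unidentified."""
        return Lineage(tuple(n if r <= depth else None for r, n in zip(RANKS, self.names)))

    def to_string(self) -> str:
        return ";".join(n if n is not None else "" for n in self.names)

    @classmethod
    def from_names(cls, *names: Optional[str]) -> "Lineage":
        padded = tuple(names) + (None,) * (len(RANKS) - len(names))
        return cls(padded)


def parse_lineage(
    text: str,
    placeholder_tokens: frozenset[str] = DEFAULT_PLACEHOLDER_TOKENS,
) -> Lineage:
    """Parse a semicolon-delimited seven-field lineage string.

    Empty fields and placeholder tokens ("unidentified", "sp.",
    "incertae sedis"; case-insensitive) become unidentified slots.
    """
    fields = text.split(";")
    if len(fields) != len(RANKS):
        raise CorpusError(
            f"lineage must have {len(RANKS)} semicolon-separated fields, got {len(fields)}: {text!r}"
        )
    names: list[Optional[str]] = []
    for raw in fields:
        name = raw.strip()
        if name.lower() in placeholder_tokens:
            names.append(None)
        else:
            names.append(name)
    return Lineage(tuple(names))


def annotation_depth(lineage: Lineage) -> Rank:
    """Deepest identified rank; requires an identified kingdom."""
    if not lineage.is_identified(Rank.KINGDOM):
        raise CorpusError("lineage has no identified kingdom; depth undefined")
    depth = lineage.depth()
    assert depth is not None
    return depth


def is_fully_identified(
    lineage: Lineage,
    provisional_pattern: re.Pattern[str] = DEFAULT_PROVISIONAL_PATTERN,
) -> bool:
    """True iff the species slot holds a non-provisional binomial name."""
    species = lineage.name_at(Rank.SPECIES)
    if species is None:
        return False
    return provisional_pattern.search(species) is None


@dataclass(frozen=True)
class SequenceRecord:
    """One corpus entry: sequence plus deposition metadata.

    ``country``, ``journal`` and ``study_id`` are ``None`` when absent — never
    empty strings — because downstream scoring rules test for absence.
    """

    accession: str
    sequence: str
    release_date: dt.date
    lineage: Lineage
    country: Optional[str] = None
    journal: Optional[str] = None
    study_id: Optional[str] = None

    @property
    def year(self) -> int:
        return self.release_date.year

    def __post_init__(self) -> None:
        if not self.accession:
            raise CorpusError("accession must be non-empty")
        if not self.sequence:
            raise CorpusError(f"{self.accession}: sequence must be non-empty")
        bad = set(self.sequence.upper()) - IUPAC_NUCLEOTIDES
        if bad:
            raise CorpusError(
                f"{self.accession}: unknown nucleotide symbol(s) {sorted(bad)!r}"
            )


def _parse_date(text: str, accession: str) -> dt.date:
    try:
        return dt.date.fromisoformat(text)
    except ValueError as exc:
        raise CorpusError(f"{accession}: unparseable release date {text!r}") from exc


def _read_fasta(fasta_path: Path) -> dict[str, str]:
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in sequences:
            raise CorpusError(f"duplicate accession in FASTA: {rec.id}")
        sequences[rec.id] = str(rec.seq)
    return sequences


def read_corpus(fasta_path: str | Path, metadata_path: str | Path) -> list[SequenceRecord]:
    """Join a FASTA file with its metadata TSV into SequenceRecords.

    FASTA ids and the metadata accession column must be in bijection; record
    order follows the metadata rows.  Missing release dates are rejected: the
    temporal audit is meaningless without them.
    """
    fasta_path, metadata_path = Path(fasta_path), Path(metadata_path)
    sequences = _read_fasta(fasta_path)

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(metadata_path, encoding="utf-8", newline="") as handle:
        header = handle.readline().rstrip("\r\n").split("\t")
        if tuple(header) != METADATA_COLUMNS:
            raise CorpusError(
                f"metadata header must be {METADATA_COLUMNS}, got {tuple(header)}"
            )
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(METADATA_COLUMNS):
                raise CorpusError(
                    f"{metadata_path}:{lineno}: expected {len(METADATA_COLUMNS)} fields, "
                    f"got {len(fields)}"
                )
            accession, date_s, lineage_s, country, journal, study_id = fields
            if accession in seen:
                raise CorpusError(f"duplicate accession in metadata: {accession}")
            seen.add(accession)
            if accession not in sequences:
                raise CorpusError(f"metadata accession missing from FASTA: {accession}")
            if not date_s:
                raise CorpusError(f"{accession}: missing release date")
            records.append(
                SequenceRecord(
                    accession=accession,
                    sequence=sequences[accession],
                    release_date=_parse_date(date_s, accession),
                    lineage=parse_lineage(lineage_s),
                    country=country or None,
                    journal=journal or None,
                    study_id=study_id or None,
                )
            )
    extra = set(sequences) - seen
    if extra:
        raise CorpusError(f"FASTA accession(s) missing from metadata: {sorted(extra)}")
    return records


def write_corpus(
    records: Sequence[SequenceRecord],
    fasta_path: str | Path,
    metadata_path: str | Path,
) -> None:
    """Write records back to FASTA + metadata TSV (inverse of read_corpus)."""
    bio_records = [
        _BioSeqRecord(Seq(r.sequence), id=r.accession, description="") for r in records
    ]
    SeqIO.write(bio_records, str(fasta_path), "fasta")
    with open(metadata_path, "w", encoding="utf-8", newline="\n") as handle:
        handle.write("\t".join(METADATA_COLUMNS) + "\n")
        for r in records:
            handle.write(
                "\t".join(
                    [
                        r.accession,
                        r.release_date.isoformat(),
                        r.lineage.to_string(),
                        r.country or "",
                        r.journal or "",
                        r.study_id or "",
                    ]
                )
                + "\n"
            )
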