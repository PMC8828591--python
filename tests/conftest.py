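from __future__ import annotations

import datetime as dt

import pytest

from annogap.corpus import Lineage, SequenceRecord, parse_lineage

AMANITA = "Fungi;Basidiomycota;Agaricomycetes;Agaricales;Amanitaceae;Amanita;Amanita muscaria"
CANTHARELLUS = (
    "Fungi;Basidiomycota;Agaricomycetes;Cantharellales;Cantharellaceae;"
    "Cantharellus;Cantharellus cibarius"
)
KINGDOM_ONLY = "Fungi;;;;;;"


def make_record(
    accession: str,
    sequence: str = "ACGTACGTACGTACGTACGT",
    date: str = "2010-06-01",
    lineage: str = KINGDOM_ONLY,
    country: str | None = None,
    journal: str | None = None,
    study_id: str | None = None,
) -> SequenceRecord:
    return SequenceRecord(
        accession=accession,
        sequence=sequence,
        release_date=dt.date.fromisoformat(date),
        lineage=parse_lineage(lineage),
        country=country,
        journal=journal,
        study_id=study_id,
    )


@pytest.fixture
def amanita_lineage() -> Lineage:
    return parse_lineage(AMANITA)


@pytest.fixture
def cantharellus_lineage() -> Lineage:
    return parse_lineage(CANTHARELLUS)


@pytest.fixture
def kingdom_lineage() -> Lineage:
    return parse_lineage(KINGDOM_ONLY)


@pytest.fixture
def three_record_corpus(tmp_path):
    """A 3-entry FASTA + matching TSV on disk; returns (fasta, tsv) paths."""
    fasta = tmp_path / "corpus.fasta"
    tsv = tmp_path / "metadata.tsv"
    fasta.write_text(
        ">ACC1\nACGTACGTACGTACGT\n"
        ">ACC2\nTTTTACGTACGTACGTAA\n"
        ">ACC3\nACGTNNACGTACGTACGT\n"
    )
    tsv.write_text(
        "accession\trelease_date\tlineage\tcountry\tjournal\tstudy_id\n"
        f"ACC1\t2010-06-01\t{AMANITA}\tSweden\tPlaceholder Mycology Bulletin\tST01\n"
        f"ACC2\t2015-01-30\t{KINGDOM_ONLY}\t\t\t\n"
        "ACC3\t2008-11-12\tFungi;Ascomycota;;;;;\tEstonia\tGeneral Science Letters\tST02\n"
    )
    return fasta, tsv
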