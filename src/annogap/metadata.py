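"""Journal-based mycologist scoring, country comparison and yearly trend."""

from __future__ import annotations

import re
import string
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .audit import AuditResult, Classification
from .corpus import Rank, SequenceRecord, is_fully_identified

__all__ = [
    "JournalList",
    "normalize_journal_name",
    "is_mycology_journal",
    "MycologistFractions",
    "mycologist_fractions",
    "country_comparison",
    "yearly_fn_trend",
]

_PUNCT_TABLE = str.maketrans({c: " " for c in string.punctuation})
_WS = re.compile(r"\s+")


def normalize_journal_name(name: str) -> str:
    """Case-fold, map '&' to 'and', strip punctuation, collapse whitespace."""
    name = name.replace("&", " and ")
    name = name.translate(_PUNCT_TABLE)
    return _WS.sub(" ", name).strip().casefold()


@dataclass(frozen=True)
class JournalList:
    """Set of journal names scored as mycological (stored normalized)."""

    names: frozenset[str]

    @classmethod
    def from_names(cls, names: Iterable[str]) -> "JournalList":
        return cls(frozenset(normalize_journal_name(n) for n in names if n.strip()))

    @classmethod
    def from_file(cls, path: str | Path) -> "JournalList":
        """Read one journal name per line; '#' starts a comment."""
        names = []
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.split("#", 1)[0].strip()
            if line:
                names.append(line)
        return cls.from_names(names)

    def __contains__(self, name: str) -> bool:
        return normalize_journal_name(name) in self.names


def is_mycology_journal(journal: Optional[str], journals: JournalList) -> bool:
    """Absent journals (direct submissions) score as non-mycological."""
    if journal is None or not journal.strip():
        return False
    return journal in journals


@dataclass(frozen=True)
class MycologistFractions:
    """Fractions are None when the denominator is empty."""

    fn_close_myc_fraction: Optional[float]
    n_fn_close: int
    fully_identified_myc_fraction: Optional[float]
    n_fully_identified: int


def mycologist_fractions(
    results: Sequence[AuditResult],
    records: Sequence[SequenceRecord],
    journals: JournalList,
) -> MycologistFractions:
    """Mycologist share among FN_CLOSE queries and among fully identified records."""
    by_acc = {r.accession: r for r in records}
    fn_close = [
        by_acc[res.accession]
        for res in results
        if res.classification is Classification.FN_CLOSE
    ]
    fully_ident = [r for r in records if is_fully_identified(r.lineage)]

    def _frac(group: list[SequenceRecord]) -> Optional[float]:
        if not group:
            return None
        return sum(1 for r in group if is_mycology_journal(r.journal, journals)) / len(group)

    return MycologistFractions(
        fn_close_myc_fraction=_frac(fn_close),
        n_fn_close=len(fn_close),
        fully_identified_myc_fraction=_frac(fully_ident),
        n_fully_identified=len(fully_ident),
    )


def country_comparison(records: Sequence[SequenceRecord], top: int = 15) -> pd.DataFrame:
    """Compare countries of collection between annotated and kingdom-level records.

    Restricted to records with a known country; per country, the proportion
    among records annotated to at least phylum level and among kingdom-level
    records.  Ranked by the phylum-level proportion (descending, ties by
    country name), top ``top`` rows kept.  Counts and group totals are
    included so every fraction carries its denominator.
    """
    known = [r for r in records if r.country is not None]
    annotated = [r for r in known if (d := r.lineage.depth()) is not None and d >= Rank.PHYLUM]
    kingdom = [r for r in known if r.lineage.is_kingdom_level()]

    n_ann, n_kin = len(annotated), len(kingdom)
    countries = sorted({r.country for r in known})
    rows = []
    for country in countries:
        c_ann = sum(1 for r in annotated if r.country == country)
        c_kin = sum(1 for r in kingdom if r.country == country)
        rows.append(
            {
                "country": country,
                "n_annotated": c_ann,
                "prop_annotated": c_ann / n_ann if n_ann else 0.0,
                "n_kingdom": c_kin,
                "prop_kingdom": c_kin / n_kin if n_kin else 0.0,
                "total_annotated": n_ann,
                "total_kingdom": n_kin,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "country",
            "n_annotated",
            "prop_annotated",
            "n_kingdom",
            "prop_kingdom",
            "total_annotated",
            "total_kingdom",
        ],
    )
    if frame.empty:
        return frame
    frame = frame.sort_values(
        ["prop_annotated", "country"], ascending=[False, True], kind="mergesort"
    ).head(top)
    return frame.reset_index(drop=True)


def yearly_fn_trend(
    results: Sequence[AuditResult],
    records: Sequence[SequenceRecord],
    years: tuple[int, int] = (2001, 2020),
) -> pd.DataFrame:
    """Per-year FN fractions among that year's kingdom-level queries.

    Years without queries get NaN fractions ("absent"), not zero.
    """
    by_acc = {r.accession: r for r in records}
    start, end = years
    rows = []
    for year in range(start, end + 1):
        year_results = [res for res in results if by_acc[res.accession].year == year]
        n = len(year_results)
        if n == 0:
            rows.append(
                {"year": year, "n_queries": 0, "fn_close_frac": float("nan"),
                 "fn_reasonable_frac": float("nan")}
            )
            continue
        n_close = sum(
            1 for r in year_results if r.classification is Classification.FN_CLOSE
        )
        n_reason = sum(
            1 for r in year_results if r.classification is Classification.FN_REASONABLE
        )
        rows.append(
            {
                "year": year,
                "n_queries": n,
                "fn_close_frac": n_close / n,
                "fn_reasonable_frac": n_reason / n,
            }
        )
    return pd.DataFrame(rows, columns=["year", "n_queries", "fn_close_frac", "fn_reasonable_frac"])
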