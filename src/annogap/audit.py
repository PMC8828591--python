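"""Deposition-history replay: classify kingdom-level queries and aggregate.

For every record annotated only at kingdom level, the audit asks which
co-clustered records were already available (released at least ``lag_days``
earlier, default 7) and whether any of them carried a deeper annotation:

* FN_CLOSE      — an available co-member of the query's species hypothesis is
                  annotated beyond kingdom (a top-scoring match would have
                  revealed a name);
* FN_REASONABLE — not FN_CLOSE, but an available co-member of the query's
                  compound cluster is annotated beyond kingdom (a name was
                  further down the hit list);
* TP            — no qualifying better-annotated match existed: a genuine
                  dark-taxon candidate at the time of deposition.
"""

from __future__ import annotations

import datetime as dt
import enum
import json
import statistics
from dataclasses import dataclass
from typing import Optional, Sequence

from .clustering import ClusterSet
from .consensus import has_conflict_at
from .corpus import Lineage, Rank, RANKS, SequenceRecord

__all__ = [
    "AvailabilityPolicy",
    "Classification",
    "AuditResult",
    "AuditReport",
    "available_before",
    "classify_query",
    "audit_corpus",
    "write_results_tsv",
    "write_report_json",
]


class Classification(str, enum.Enum):
    TP = "TP"
    FN_CLOSE = "FN_CLOSE"
    FN_REASONABLE = "FN_REASONABLE"


@dataclass(frozen=True)
class AvailabilityPolicy:
    """A reference is available to a query iff released >= lag_days earlier."""

    lag_days: int = 7

    def __post_init__(self) -> None:
        if self.lag_days < 0:
            raise ValueError("lag_days must be non-negative")

    def is_available(self, reference_date: dt.date, query_date: dt.date) -> bool:
        return (query_date - reference_date).days >= self.lag_days


@dataclass(frozen=True)
class AuditResult:
    """Per-query classification plus availability and hit-list composition.

    ``rank_available_*[r]`` is True iff some available co-member carries an
    identified name at exactly rank ``r`` (close = SH co-members,
    reasonable = compound-cluster co-members).  ``hitlist_*_props[r]`` is the
    fraction of available co-members annotated to depth >= r, or None when no
    co-member is available.
    """

    accession: str
    classification: Classification
    rank_available_close: dict[Rank, bool]
    rank_available_reasonable: dict[Rank, bool]
    hitlist_close_props: Optional[dict[Rank, float]]
    hitlist_reasonable_props: Optional[dict[Rank, float]]
    n_available_sh: int
    n_available_cc: int


def _safe_depth(lineage: Lineage) -> Optional[Rank]:
    return lineage.depth()


def available_before(
    records: Sequence[SequenceRecord],
    query: SequenceRecord,
    policy: AvailabilityPolicy,
) -> set[str]:
    """Accessions of records available to ``query`` under the policy.

    The query itself is never available to itself.
    """
    return {
        r.accession
        for r in records
        if r.accession != query.accession
        and policy.is_available(r.release_date, query.release_date)
    }


def _hitlist_props(co_members: list[SequenceRecord]) -> Optional[dict[Rank, float]]:
    if not co_members:
        return None
    n = len(co_members)
    depths = [_safe_depth(r.lineage) for r in co_members]
    return {
        rank: sum(1 for d in depths if d is not None and d >= rank) / n for rank in RANKS
    }


def _rank_flags(co_members: list[SequenceRecord]) -> dict[Rank, bool]:
    flags = {rank: False for rank in RANKS}
    for r in co_members:
        for rank in r.lineage.identified_ranks():
            flags[rank] = True
    return flags


def classify_query(
    query: SequenceRecord,
    records_by_acc: dict[str, SequenceRecord],
    clusters: ClusterSet,
    policy: AvailabilityPolicy,
) -> AuditResult:
    """Classify one kingdom-level query against its SH and compound cluster."""
    depth = query.lineage.depth()
    if depth != Rank.KINGDOM:
        raise ValueError(
            f"{query.accession}: query must be annotated only at kingdom level"
        )

    def _available(accessions: list[str]) -> list[SequenceRecord]:
        out = []
        for acc in accessions:
            rec = records_by_acc[acc]
            if policy.is_available(rec.release_date, query.release_date):
                out.append(rec)
        return out

    sh_avail = _available(clusters.co_members_sh(query.accession))
    cc_avail = _available(clusters.co_members_compound(query.accession))

    def _annotated(recs: list[SequenceRecord]) -> bool:
        return any(
            (d := _safe_depth(r.lineage)) is not None and d > Rank.KINGDOM for r in recs
        )

    if _annotated(sh_avail):
        classification = Classification.FN_CLOSE
    elif _annotated(cc_avail):
        classification = Classification.FN_REASONABLE
    else:
        classification = Classification.TP

    return AuditResult(
        accession=query.accession,
        classification=classification,
        rank_available_close=_rank_flags(sh_avail),
        rank_available_reasonable=_rank_flags(cc_avail),
        hitlist_close_props=_hitlist_props(sh_avail),
        hitlist_reasonable_props=_hitlist_props(cc_avail),
        n_available_sh=len(sh_avail),
        n_available_cc=len(cc_avail),
    )


@dataclass
class AuditReport:
    """Corpus-level aggregation of the per-query audit results.

    Fractions are None ("absent") when their denominator is empty.  Cluster
    sizes at deposition time are counted over available co-members; both the
    query-exclusive and query-inclusive readings are exported.
    """

    n_queries: int
    counts: dict[str, int]
    fractions: dict[str, Optional[float]]
    rank_availability_close: dict[str, Optional[float]]
    rank_availability_reasonable: dict[str, Optional[float]]
    hitlist_mean_close: dict[str, Optional[float]]
    hitlist_mean_reasonable: dict[str, Optional[float]]
    n_queries_with_close_hits: int
    n_queries_with_reasonable_hits: int
    median_sh_size_excl_query: Optional[float]
    median_sh_size_incl_query: Optional[float]
    mean_cc_size_excl_query: Optional[float]
    mean_cc_size_incl_query: Optional[float]
    phylum_conflict_rate_sh: Optional[float]
    phylum_conflict_rate_cc: Optional[float]
    n_sh: int = 0
    n_cc: int = 0

    def to_dict(self) -> dict:
        return {
            "n_queries": self.n_queries,
            "counts": self.counts,
            "fractions": self.fractions,
            "rank_availability_close": self.rank_availability_close,
            "rank_availability_reasonable": self.rank_availability_reasonable,
            "hitlist_mean_close": self.hitlist_mean_close,
            "hitlist_mean_reasonable": self.hitlist_mean_reasonable,
            "n_queries_with_close_hits": self.n_queries_with_close_hits,
            "n_queries_with_reasonable_hits": self.n_queries_with_reasonable_hits,
            "median_sh_size_excl_query": self.median_sh_size_excl_query,
            "median_sh_size_incl_query": self.median_sh_size_incl_query,
            "mean_cc_size_excl_query": self.mean_cc_size_excl_query,
            "mean_cc_size_incl_query": self.mean_cc_size_incl_query,
            "phylum_conflict_rate_sh": self.phylum_conflict_rate_sh,
            "phylum_conflict_rate_cc": self.phylum_conflict_rate_cc,
            "n_sh": self.n_sh,
            "n_cc": self.n_cc,
        }


def _mean_over(values: list[float]) -> Optional[float]:
    return sum(values) / len(values) if values else None


def audit_corpus(
    records: Sequence[SequenceRecord],
    clusters: ClusterSet,
    policy: Optional[AvailabilityPolicy] = None,
) -> tuple[AuditReport, list[AuditResult]]:
    """Run the audit over every kingdom-level record and aggregate.

    Per-rank availability fractions are computed over ALL kingdom-level
    queries (queries with no available co-member count as all-false); hit-list
    means only over queries with a non-empty respective hit list.
    """
    policy = policy or AvailabilityPolicy()
    by_acc = {r.accession: r for r in records}
    queries = [r for r in records if r.lineage.is_kingdom_level()]
    results = [classify_query(q, by_acc, clusters, policy) for q in queries]

    n = len(results)
    counts = {c.value: 0 for c in Classification}
    for res in results:
        counts[res.classification.value] += 1
    fractions: dict[str, Optional[float]] = {
        c: (counts[c] / n if n else None) for c in counts
    }

    def _avail_fracs(attr: str) -> dict[str, Optional[float]]:
        out: dict[str, Optional[float]] = {}
        for rank in RANKS:
            if n == 0:
                out[rank.label] = None
            else:
                out[rank.label] = sum(1 for r in results if getattr(r, attr)[rank]) / n
        return out

    def _hit_means(attr: str) -> tuple[dict[str, Optional[float]], int]:
        with_hits = [getattr(r, attr) for r in results if getattr(r, attr) is not None]
        means = {
            rank.label: _mean_over([props[rank] for props in with_hits]) for rank in RANKS
        }
        return means, len(with_hits)

    hit_close, n_close = _hit_means("hitlist_close_props")
    hit_reasonable, n_reasonable = _hit_means("hitlist_reasonable_props")

    sh_sizes = [r.n_available_sh for r in results if r.n_available_sh >= 1]
    cc_sizes = [r.n_available_cc for r in results if r.n_available_cc >= 1]

    lineages_by_sh = {
        sid: [by_acc[a].lineage for a in accs] for sid, accs in clusters.sh_members.items()
    }
    lineages_by_cc = {
        cid: [by_acc[a].lineage for a in accs]
        for cid, accs in clusters.compound_members.items()
    }
    n_sh, n_cc = len(lineages_by_sh), len(lineages_by_cc)
    conflict_sh = (
        sum(1 for lins in lineages_by_sh.values() if has_conflict_at(lins, Rank.PHYLUM)) / n_sh
        if n_sh
        else None
    )
    conflict_cc = (
        sum(1 for lins in lineages_by_cc.values() if has_conflict_at(lins, Rank.PHYLUM)) / n_cc
        if n_cc
        else None
    )

    report = AuditReport(
        n_queries=n,
        counts=counts,
        fractions=fractions,
        rank_availability_close=_avail_fracs("rank_available_close"),
        rank_availability_reasonable=_avail_fracs("rank_available_reasonable"),
        hitlist_mean_close=hit_close,
        hitlist_mean_reasonable=hit_reasonable,
        n_queries_with_close_hits=n_close,
        n_queries_with_reasonable_hits=n_reasonable,
        median_sh_size_excl_query=(statistics.median(sh_sizes) if sh_sizes else None),
        median_sh_size_incl_query=(
            statistics.median([s + 1 for s in sh_sizes]) if sh_sizes else None
        ),
        mean_cc_size_excl_query=_mean_over([float(s) for s in cc_sizes]),
        mean_cc_size_incl_query=_mean_over([float(s + 1) for s in cc_sizes]),
        phylum_conflict_rate_sh=conflict_sh,
        phylum_conflict_rate_cc=conflict_cc,
        n_sh=n_sh,
        n_cc=n_cc,
    )
    return report, results


def write_results_tsv(results: Sequence[AuditResult], path) -> None:
    """Per-query audit table (one row per kingdom-level query)."""
    cols = ["accession", "classification"]
    cols += [f"avail_close_{r.label}" for r in RANKS]
    cols += [f"avail_reasonable_{r.label}" for r in RANKS]
    cols += [f"hit_close_{r.label}" for r in RANKS]
    cols += [f"hit_reasonable_{r.label}" for r in RANKS]
    cols += ["n_available_sh", "n_available_cc"]

    def _fmt_prop(props: Optional[dict[Rank, float]], rank: Rank) -> str:
        return "" if props is None else f"{props[rank]:.6g}"

    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        handle.write("\t".join(cols) + "\n")
        for res in results:
            row = [res.accession, res.classification.value]
            row += ["1" if res.rank_available_close[r] else "0" for r in RANKS]
            row += ["1" if res.rank_available_reasonable[r] else "0" for r in RANKS]
            row += [_fmt_prop(res.hitlist_close_props, r) for r in RANKS]
            row += [_fmt_prop(res.hitlist_reasonable_props, r) for r in RANKS]
            row += [str(res.n_available_sh), str(res.n_available_cc)]
            handle.write("\t".join(row) + "\n")


def write_report_json(report: AuditReport, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        json.dump(report.to_dict(), handle, indent=2, sort_keys=True)
        handle.write("\n")
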