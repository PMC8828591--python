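"""Conflict-aware consensus lineage assignment.

A set of member lineages is assigned to the most resolved rank at which their
identified names are compatible.  Low-resolution annotations are ignored as
long as they do not contradict: rank by rank, an empty name set leaves the
rank unidentified (and resolution continues deeper), a singleton assigns the
name, and two or more distinct names stop resolution at the rank above.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional

from .corpus import Lineage, Rank, RANKS

__all__ = ["ConsensusResult", "resolve_consensus", "has_conflict_at"]

_WS = re.compile(r"\s+")


def _norm(name: str) -> str:
    """Comparison key: collapse whitespace and casefold. No synonym logic."""
    return _WS.sub(" ", name.strip()).casefold()


def _names_at(lineages: Iterable[Lineage], rank: Rank) -> dict[str, str]:
    """Distinct identified names at a rank, keyed by normalized form.

    The representative for each key is the lexicographically smallest raw
    spelling, so the result is independent of input order.
    """
    variants: dict[str, str] = {}
    for lin in lineages:
        name = lin.name_at(rank)
        if name is None:
            continue
        cleaned = _WS.sub(" ", name.strip())
        key = _norm(name)
        if key not in variants or cleaned < variants[key]:
            variants[key] = cleaned
    return variants


@dataclass(frozen=True)
class ConsensusResult:
    lineage: Lineage
    conflict_rank: Optional[Rank] = None

    def __post_init__(self) -> None:
        if self.conflict_rank is not None:
            for r in RANKS:
                if r >= self.conflict_rank and self.lineage.is_identified(r):
                    raise ValueError(
                        "consensus must be unidentified at and below the conflict rank"
                    )


def resolve_consensus(lineages: Iterable[Lineage]) -> ConsensusResult:
    """Assign the deepest compatible consensus lineage to a set of lineages.

    Resolution proceeds from kingdom to species; the first rank carrying two
    or more distinct identified names becomes the conflict rank, below which
    everything is left unidentified.  Unidentified slots never block deeper
    assignment.
    """
    lineages = list(lineages)
    if not lineages:
        raise ValueError("cannot resolve consensus of an empty collection")

    names: list[Optional[str]] = [None] * len(RANKS)
    conflict_rank: Optional[Rank] = None
    for rank in RANKS:
        distinct = _names_at(lineages, rank)
        if len(distinct) > 1:
            conflict_rank = rank
            break
        if len(distinct) == 1:
            names[rank] = next(iter(distinct.values()))
    return ConsensusResult(lineage=Lineage(tuple(names)), conflict_rank=conflict_rank)


def has_conflict_at(lineages: Iterable[Lineage], rank: Rank) -> bool:
    """True iff two or more distinct identified names occur at ``rank``."""
    return len(_names_at(lineages, rank)) > 1
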