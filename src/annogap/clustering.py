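"""Pairwise identity and the two-level cluster structure.

Records are first grouped into *compound clusters* by a deterministic greedy
centroid pass at >=80% identity, then each compound cluster is sub-partitioned
into *species hypotheses* (SHs) by single-linkage at a distance threshold
(default 3.0%).

Identity between two sequences is computed from the optimal global alignment
under a fixed scoring (+1 match, -1 mismatch, -2 per gap column, linear), as
identical columns over alignment columns after trimming terminal-gap columns.
Ambiguity codes never count as identical.  Ties among co-optimal alignments
are broken by a fixed traceback preference (match/mismatch > gap in the first
sequence > gap in the second); to make the reported identity symmetric the
two sequences are put in a canonical order before aligning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .corpus import SequenceRecord

__all__ = [
    "ClusteringConfig",
    "ClusterSet",
    "global_identity",
    "build_compound_clusters",
    "build_species_hypotheses",
    "build_cluster_set",
]

#: SH distance-threshold ladder: 0.0% .. 3.0% in 0.5% steps.
SH_THRESHOLD_LADDER = tuple(round(0.005 * i, 3) for i in range(7))

_MATCH = 1
_MISMATCH = -1
_GAP = -2

# Nucleotide encoding: A,C,G,T -> 0..3; every other IUPAC letter -> >=4 so it
# can never produce an identical column.
_CODE = np.full(256, 15, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i
for _i, _c in enumerate("URYSWKMBDHVN"):
    _CODE[ord(_c)] = 4 + _i
    _CODE[ord(_c.lower())] = 4 + _i


def _align_stats(a: np.ndarray, b: np.ndarray) -> tuple[int, int]:
    """Needleman-Wunsch with deterministic traceback.

    Returns (identical columns, alignment columns after trimming terminal-gap
    columns).  Match requires equal unambiguous codes (< 4).  Pointer
    preference on score ties: diagonal, then gap-in-a (consume b), then
    gap-in-b (consume a).
    """
    n = a.shape[0]
    m = b.shape[0]
    score = np.zeros((n + 1, m + 1), dtype=np.int32)
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 left (gap in a), 2 up (gap in b)
    for j in range(1, m + 1):
        score[0, j] = _GAP * j
        ptr[0, j] = 1
    for i in range(1, n + 1):
        score[i, 0] = _GAP * i
        ptr[i, 0] = 2
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            sub = _MATCH if (ai == b[j - 1] and ai < 4 and b[j - 1] < 4) else _MISMATCH
            diag = score[i - 1, j - 1] + sub
            left = score[i, j - 1] + _GAP
            up = score[i - 1, j] + _GAP
            best = diag
            p = 0
            if left > best:
                best = left
                p = 1
            if up > best:
                best = up
                p = 2
            score[i, j] = best
            ptr[i, j] = p

    # Traceback: record per-column flags (gap?, identical?) in reverse order.
    ncols = 0
    gaps = np.zeros(n + m, dtype=np.int8)
    ident = np.zeros(n + m, dtype=np.int8)
    i, j = n, m
    while i > 0 or j > 0:
        p = ptr[i, j]
        if p == 0:
            if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                ident[ncols] = 1
            i -= 1
            j -= 1
        elif p == 1:
            gaps[ncols] = 1
            j -= 1
        else:
            gaps[ncols] = 1
            i -= 1
        ncols += 1

    # Trim terminal-gap columns (columns is reversed; ends are symmetric).
    lo = 0
    hi = ncols - 1
    while lo <= hi and gaps[lo] == 1:
        lo += 1
    while hi >= lo and gaps[hi] == 1:
        hi -= 1
    n_ident = 0
    for k in range(lo, hi + 1):
        n_ident += ident[k]
    return n_ident, hi - lo + 1


_align_stats_py = _align_stats
try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _align_stats = njit(cache=True, nogil=True)(_align_stats_py)
except Exception:  # pragma: no cover
    pass


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ClusteringConfig:
    """Thresholds and scoring for the two-level clustering."""

    compound_identity_threshold: float = 0.80
    sh_distance_threshold: float = 0.030
    ladder_mode: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.compound_identity_threshold < 1.0:
            raise ValueError("compound_identity_threshold must be in (0, 1)")
        if not 0.0 <= self.sh_distance_threshold <= 1.0 - self.compound_identity_threshold:
            raise ValueError(
                "sh_distance_threshold must lie in [0, 1 - compound_identity_threshold]"
            )
        if self.ladder_mode and not any(
            abs(self.sh_distance_threshold - t) < 1e-12 for t in SH_THRESHOLD_LADDER
        ):
            raise ValueError(
                f"sh_distance_threshold must be on the ladder {SH_THRESHOLD_LADDER}"
            )


def global_identity(a: str, b: str, config: Optional[ClusteringConfig] = None) -> float:
    """Fraction of identical columns in the optimal global alignment of a and b.

    The denominator excludes terminal-gap columns, so length differences do
    not depress identity; internal gap columns count as non-identical.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    # Canonical argument order makes the tie-broken identity symmetric.
    ea, eb = _encode(a), _encode(b)
    x, y = (ea, eb) if _enc_key(ea) <= _enc_key(eb) else (eb, ea)
    n_ident, n_cols = _align_stats(x, y)
    if n_cols <= 0:
        return 0.0
    return n_ident / n_cols


def _processing_order(records: Sequence[SequenceRecord]) -> list[SequenceRecord]:
    # Decreasing sequence length, ties by ascending accession.
    return sorted(records, key=lambda r: (-len(r.sequence), r.accession))


def build_compound_clusters(
    records: Sequence[SequenceRecord],
    config: Optional[ClusteringConfig] = None,
) -> list[list[str]]:
    """Greedy centroid clustering at the compound identity threshold.

    Records are processed by decreasing length (ties by accession); each joins
    the first centroid, in founding order, with identity >= threshold, else
    founds a new centroid.  Returns accession lists in founding order.
    """
    config = config or ClusteringConfig()
    centroids: list[np.ndarray] = []
    clusters: list[list[str]] = []
    for rec in _processing_order(records):
        enc = _encode(rec.sequence)
        placed = False
        for k, cent in enumerate(centroids):
            x, y = (enc, cent) if _enc_key(enc) <= _enc_key(cent) else (cent, enc)
            n_ident, n_cols = _align_stats(x, y)
            if n_cols > 0 and n_ident / n_cols >= config.compound_identity_threshold:
                clusters[k].append(rec.accession)
                placed = True
                break
        if not placed:
            centroids.append(enc)
            clusters.append([rec.accession])
    return clusters


def _enc_key(enc: np.ndarray) -> tuple[int, bytes]:
    return (len(enc), enc.tobytes())


def build_species_hypotheses(
    members: Sequence[SequenceRecord],
    config: Optional[ClusteringConfig] = None,
) -> list[list[str]]:
    """Single-linkage components at the SH distance threshold.

    An edge joins a, b iff 1 - identity(a, b) <= threshold; SHs are the
    connected components.  Pairs already connected are skipped (redundant
    edges cannot change components), which prunes most alignments on
    well-separated corpora.
    """
    config = config or ClusteringConfig()
    order = _processing_order(members)
    n = len(order)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    encoded = [_encode(r.sequence) for r in order]
    keys = [_enc_key(e) for e in encoded]
    for i in range(n):
        for j in range(i + 1, n):
            ri, rj = find(i), find(j)
            if ri == rj:
                continue
            x, y = (encoded[i], encoded[j]) if keys[i] <= keys[j] else (encoded[j], encoded[i])
            n_ident, n_cols = _align_stats(x, y)
            ident = n_ident / n_cols if n_cols > 0 else 0.0
            if 1.0 - ident <= config.sh_distance_threshold + 1e-12:
                parent[max(ri, rj)] = min(ri, rj)

    groups: dict[int, list[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(order[i].accession)
    # Deterministic order: by first-processed member.
    return [groups[root] for root in sorted(groups)]


@dataclass
class ClusterSet:
    """Partition of a corpus into compound clusters, each split into SHs."""

    compound_members: dict[str, list[str]]
    sh_members: dict[str, list[str]]
    accession_to_compound: dict[str, str] = field(init=False)
    accession_to_sh: dict[str, str] = field(init=False)

    def __post_init__(self) -> None:
        self.accession_to_compound = {
            acc: cid for cid, accs in self.compound_members.items() for acc in accs
        }
        self.accession_to_sh = {
            acc: sid for sid, accs in self.sh_members.items() for acc in accs
        }
        self.validate()

    def validate(self) -> None:
        all_cc = [a for accs in self.compound_members.values() for a in accs]
        if len(all_cc) != len(set(all_cc)):
            raise ValueError("compound clusters are not disjoint")
        all_sh = [a for accs in self.sh_members.values() for a in accs]
        if sorted(all_sh) != sorted(all_cc):
            raise ValueError("SHs do not partition the corpus")
        for sid, accs in self.sh_members.items():
            owners = {self.accession_to_compound[a] for a in accs}
            if len(owners) != 1:
                raise ValueError(f"SH {sid} spans multiple compound clusters")

    def compound_of(self, accession: str) -> str:
        return self.accession_to_compound[accession]

    def sh_of(self, accession: str) -> str:
        return self.accession_to_sh[accession]

    def co_members_sh(self, accession: str) -> list[str]:
        return [a for a in self.sh_members[self.sh_of(accession)] if a != accession]

    def co_members_compound(self, accession: str) -> list[str]:
        return [a for a in self.compound_members[self.compound_of(accession)] if a != accession]


def build_cluster_set(
    records: Sequence[SequenceRecord],
    config: Optional[ClusteringConfig] = None,
) -> ClusterSet:
    """Run both clustering levels and label clusters deterministically."""
    config = config or ClusteringConfig()
    by_acc = {r.accession: r for r in records}
    compound = build_compound_clusters(records, config)
    compound_members: dict[str, list[str]] = {}
    sh_members: dict[str, list[str]] = {}
    for i, accs in enumerate(compound):
        cid = f"CC{i:05d}"
        compound_members[cid] = list(accs)
        shs = build_species_hypotheses([by_acc[a] for a in accs], config)
        for j, sh in enumerate(shs):
            sh_members[f"{cid}.SH{j:03d}"] = list(sh)
    return ClusterSet(compound_members=compound_members, sh_members=sh_members)


def write_cluster_tsv(clusters: ClusterSet, path) -> None:
    """Write accession -> compound_id, sh_id assignments as TSV."""
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        handle.write("accession\tcompound_id\tsh_id\n")
        for sid in sorted(clusters.sh_members):
            cid = sid.split(".")[0]
            for acc in clusters.sh_members[sid]:
                handle.write(f"{acc}\t{cid}\t{sid}\n")
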