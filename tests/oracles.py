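"""Independent brute-force oracles used to validate the pipeline.

These are written against the operation contracts only and deliberately share
no code with the package internals: a plain-list Needleman-Wunsch that builds
explicit alignment strings, a networkx connected-components clustering oracle,
and a pairwise classification oracle that bypasses the cluster structure.
"""

from __future__ import annotations

import networkx as nx

MATCH, MISMATCH, GAP = 1, -1, -2
_UNAMBIGUOUS = set("ACGT")


def oracle_align(a: str, b: str) -> tuple[str, str]:
    """Optimal global alignment with tie preference diag > gap-in-a > gap-in-b."""
    a, b = a.upper(), b.upper()
    n, m = len(a), len(b)
    score = [[0] * (m + 1) for _ in range(n + 1)]
    move = [[None] * (m + 1) for _ in range(n + 1)]
    for j in range(1, m + 1):
        score[0][j] = GAP * j
        move[0][j] = "left"
    for i in range(1, n + 1):
        score[i][0] = GAP * i
        move[i][0] = "up"
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            both_plain = a[i - 1] in _UNAMBIGUOUS and b[j - 1] in _UNAMBIGUOUS
            sub = MATCH if (a[i - 1] == b[j - 1] and both_plain) else MISMATCH
            options = [
                (score[i - 1][j - 1] + sub, "diag"),
                (score[i][j - 1] + GAP, "left"),  # gap in a, consume b
                (score[i - 1][j] + GAP, "up"),  # gap in b, consume a
            ]
            best = max(opt[0] for opt in options)
            for val, mv in options:  # first in preference order wins ties
                if val == best:
                    score[i][j] = val
                    move[i][j] = mv
                    break
    row_a, row_b = [], []
    i, j = n, m
    while i > 0 or j > 0:
        mv = move[i][j]
        if mv == "diag":
            row_a.append(a[i - 1])
            row_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif mv == "left":
            row_a.append("-")
            row_b.append(b[j - 1])
            j -= 1
        else:
            row_a.append(a[i - 1])
            row_b.append("-")
            i -= 1
    return "".join(reversed(row_a)), "".join(reversed(row_b))


def oracle_identity(a: str, b: str) -> float:
    """Identity over alignment columns after trimming terminal-gap columns."""
    if (len(a), a.upper()) > (len(b), b.upper()):
        a, b = b, a
    row_a, row_b = oracle_align(a, b)
    cols = list(zip(row_a, row_b))
    while cols and "-" in cols[0]:
        cols.pop(0)
    while cols and "-" in cols[-1]:
        cols.pop()
    if not cols:
        return 0.0
    ident = sum(1 for x, y in cols if x == y and x in _UNAMBIGUOUS)
    return ident / len(cols)


def oracle_single_linkage(accessions, distance, threshold: float):
    """Connected components of the thresholded distance graph (networkx)."""
    graph = nx.Graph()
    graph.add_nodes_from(accessions)
    for i, x in enumerate(accessions):
        for y in accessions[i + 1 :]:
            if distance(x, y) <= threshold + 1e-12:
                graph.add_edge(x, y)
    return [sorted(c) for c in nx.connected_components(graph)]


def oracle_classify_pairwise(records, identity, lag_days: int = 7,
                             close: float = 0.97, reasonable: float = 0.80):
    """Classify kingdom-level queries by scanning all pairs directly.

    Bypasses the cluster structure entirely: a qualifying close (reasonable)
    match is any record available >= lag_days earlier, annotated beyond
    kingdom, with pairwise identity >= 97% (>= 80%).
    """
    from annogap.corpus import Rank

    out = {}
    for q in records:
        if not q.lineage.is_kingdom_level():
            continue
        found_close = found_reasonable = False
        for r in records:
            if r.accession == q.accession:
                continue
            if (q.release_date - r.release_date).days < lag_days:
                continue
            depth = r.lineage.depth()
            if depth is None or depth <= Rank.KINGDOM:
                continue
            ident = identity(q.sequence, r.sequence)
            if ident >= close:
                found_close = True
                break
            if ident >= reasonable:
                found_reasonable = True
        out[q.accession] = (
            "FN_CLOSE" if found_close
            else "FN_REASONABLE" if found_reasonable
            else "TP"
        )
    return out
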