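"""Generalized Sequential Pattern (GSP) mining baseline.

The comparator treats the query keywords as singleton items and, for each
query, the retrieved passages of every document — ordered by character
offset — as that document's data sequence. Mining is level-wise: frequent
1-sequences seed candidate 2-sequences, frequent (l-1)-sequences seed
candidates of length l (Apriori pruning: every (l-1)-subsequence must be
frequent), and support is the number of documents whose sequence contains
the candidate. A candidate is contained if its keywords can be assigned to
passages at non-decreasing positions, so both a single passage holding all
keywords and keywords scattered across later and later passages count.
That scattered (cross-passage) match is exactly the failure mode that
makes document-level GSP re-ranking weaker than the passage-level factor
model, and it is reproduced deliberately.

The minimum support is data-driven: the supports of all candidate
subsequences form an empirical distribution whose 2.5th percentile (the
lower bound of a central 95% interval, linearly interpolated, floored at
1) is the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .io import RunEntry, TermFileEntry
from .query import KeywordSequence


@dataclass(frozen=True)
class DataSequence:
    """Per-document ordered keyword stem-sets of its retrieved passages."""

    doc_id: str
    elements: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("a data sequence needs at least one element")


def contains_sequence(seq: DataSequence, cand: tuple[int, ...], keywords: KeywordSequence) -> bool:
    """True iff candidate keywords appear at non-decreasing element positions."""
    pos = 0
    n_el = len(seq.elements)
    for idx in cand:
        stem = keywords.keywords[idx]
        while pos < n_el and stem not in seq.elements[pos]:
            pos += 1
        if pos == n_el:
            return False
        # same element may serve the next keyword too (p_i <= p_{i+1})
    return True


def build_sequences(
    run: Sequence[RunEntry],
    term_entries: Sequence[TermFileEntry],
) -> list[DataSequence]:
    """Group one topic's retrieved passages into per-document sequences.

    Elements are ordered by passage offset within each document; documents
    appear in order of their best (lowest) rank.
    """
    stems_by_rank = {e.passage_rank: e.found_stems for e in term_entries}
    per_doc: dict[str, list[tuple[int, frozenset[str]]]] = {}
    doc_best_rank: dict[str, int] = {}
    for e in sorted(run, key=lambda e: e.rank):
        if e.rank not in stems_by_rank:
            raise KeyError(f"run rank {e.rank} missing from term file")
        per_doc.setdefault(e.doc_id, []).append((e.offset, frozenset(stems_by_rank[e.rank])))
        doc_best_rank.setdefault(e.doc_id, e.rank)
    sequences = []
    for doc_id in sorted(per_doc, key=doc_best_rank.get):
        elems = tuple(s for _, s in sorted(per_doc[doc_id], key=lambda t: t[0]))
        sequences.append(DataSequence(doc_id, elems))
    return sequences


def candidate_supports(
    sequences: Sequence[DataSequence],
    keywords: KeywordSequence,
    max_len: int | None = None,
) -> dict[tuple[int, ...], int]:
    """Support of every ascending-index keyword subsequence up to max_len."""
    if not sequences:
        raise ValueError("empty sequence database")
    n = keywords.n
    max_len = n if max_len is None else min(max_len, n)
    supports: dict[tuple[int, ...], int] = {}
    for length in range(1, max_len + 1):
        for cand in combinations(range(n), length):
            supports[cand] = sum(
                contains_sequence(s, cand, keywords) for s in sequences
            )
    return supports


def minimum_support(candidate_counts: Sequence[int]) -> float:
    """2.5th percentile of the empirical support distribution, floored at 1."""
    counts = np.asarray(list(candidate_counts), dtype=float)
    if counts.size == 0:
        raise ValueError("no candidate counts")
    return max(1.0, float(np.percentile(counts, 2.5)))


def gsp_mine(
    sequences: Sequence[DataSequence],
    keywords: KeywordSequence,
    min_support: float,
    max_len: int | None = None,
) -> dict[tuple[int, ...], int]:
    """Level-wise frequent-sequence mining with Apriori candidate pruning."""
    if not sequences:
        raise ValueError("empty sequence database")
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    n = keywords.n
    max_len = n if max_len is None else min(max_len, n)
    frequent: dict[tuple[int, ...], int] = {}
    level: list[tuple[int, ...]] = [(i,) for i in range(n)]
    length = 1
    while level and length <= max_len:
        survivors: list[tuple[int, ...]] = []
        for cand in level:
            support = sum(contains_sequence(s, cand, keywords) for s in sequences)
            if support >= min_support:
                frequent[cand] = support
                survivors.append(cand)
        length += 1
        if length > max_len:
            break
        freq_set = set(survivors)
        level = []
        for cand in combinations(range(n), length):
            if all(sub in freq_set for sub in combinations(cand, length - 1)):
                level.append(cand)
    return frequent


def rank_frequent_sequences(
    frequent: Mapping[tuple[int, ...], int]
) -> list[tuple[tuple[int, ...], int]]:
    """Sort by support desc, ties by length desc then enumeration order."""
    return sorted(frequent.items(), key=lambda kv: (-kv[1], -len(kv[0]), kv[0]))


def gsp_rerank(
    run: Sequence[RunEntry],
    sequences: Sequence[DataSequence],
    frequent: Mapping[tuple[int, ...], int],
    keywords: KeywordSequence,
    k: int = 10,
    label: str | None = None,
) -> list[RunEntry]:
    """Re-rank with the top-k frequent sequences under document-level containment.

    Every passage of a document shares that document's containment status,
    so a document whose keywords are scattered across passages is boosted
    even though no single passage holds them together.
    """
    from .rerank import recursive_rerank

    if not run:
        return []
    ranked = [cand for cand, _ in rank_frequent_sequences(frequent)[:k]]
    doc_contains: dict[str, tuple[bool, ...]] = {
        s.doc_id: tuple(contains_sequence(s, cand, keywords) for cand in ranked)
        for s in sequences
    }
    blank = tuple(False for _ in ranked)
    presence = {e.rank: doc_contains.get(e.doc_id, blank) for e in run}
    return recursive_rerank(run, presence, k=len(ranked), label=label)
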