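"""Okapi BM25 first-round passage retrieval.

The per-term weight is

    w = (k1+1)·tf/(K+tf) · log[ ((r+0.5)/(R-r+0.5)) / ((n-r+0.5)/(N-n-R+r+0.5)) ]
        · (k3+1)·qtf/(k3+qtf)

with K = k1·((1-b) + b·dl/avdl), natural logarithm, plus a once-per-passage
correction k2·nq·(avdl-dl)/(avdl+dl). With no relevance information
(R = r = 0) the log factor reduces to the Robertson–Sparck Jones form
ln((N-n+0.5)/(n+0.5)). Ranking is by descending weight; ties are broken by
(doc_id, offset) ascending so runs are fully deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .io import RunEntry, TermFileEntry
from .passages import CollectionIndex
from .query import KeywordSequence


@dataclass(frozen=True)
class BM25Params:
    """Tuning constants; k2 and k3 default to the fixed settings 0 and 8."""

    k1: float = 1.2
    b: float = 0.75
    k2: float = 0.0
    k3: float = 8.0

    def __post_init__(self) -> None:
        if self.k1 < 0 or self.k3 < 0:
            raise ValueError("k1 and k3 must be non-negative")


#: Named (k1, b) presets of the standard evaluation grid.
PARAM_GRID: tuple[tuple[float, float], ...] = (
    (0.4, 2.0), (0.5, 1.3), (1.0, 1.0), (1.2, 0.75), (2.0, 0.4),
)


@dataclass(frozen=True)
class RelevanceInfo:
    """Relevance-feedback counts; both zero when no judgements are used."""

    R: int = 0
    r: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.r <= self.R:
            raise ValueError("need 0 <= r <= R")


def term_weight(
    tf: float,
    qtf: float,
    dl: float,
    avdl: float,
    N: int,
    n: int,
    params: BM25Params = BM25Params(),
    relinfo: RelevanceInfo = RelevanceInfo(),
) -> float:
    if tf == 0 or qtf == 0:
        return 0.0
    if dl <= 0 or avdl <= 0:
        raise ValueError("dl and avdl must be positive")
    R, r = relinfo.R, relinfo.r
    denom = N - n - R + r + 0.5
    if denom <= 0:
        raise ValueError("BM25 log argument undefined: N-n-R+r+0.5 <= 0")
    K = params.k1 * ((1 - params.b) + params.b * dl / avdl)
    if K + tf <= 0:
        raise ValueError(f"K+tf <= 0 (K={K}); b={params.b} too large for this dl/avdl")
    tf_part = (params.k1 + 1) * tf / (K + tf)
    log_part = math.log(((r + 0.5) / (R - r + 0.5)) / ((n - r + 0.5) / denom))
    qtf_part = (params.k3 + 1) * qtf / (params.k3 + qtf)
    return tf_part * log_part * qtf_part


@dataclass(frozen=True)
class ScoredPassage:
    passage_idx: int
    weight: float
    keyword_tf: dict[str, int]


def score_passage(
    passage_idx: int,
    keywords: KeywordSequence,
    index: CollectionIndex,
    params: BM25Params = BM25Params(),
    relinfo: RelevanceInfo = RelevanceInfo(),
) -> ScoredPassage:
    passage = index.passages[passage_idx]
    dl = index.dl[passage_idx]
    weight = 0.0
    keyword_tf: dict[str, int] = {}
    for kw in keywords.keywords:
        tf = passage.stems.get(kw, 0)
        keyword_tf[kw] = tf
        if tf:
            weight += term_weight(
                tf, 1.0, dl, index.avdl, index.n_passages,
                index.df.get(kw, 0), params, relinfo,
            )
    if params.k2:
        nq = keywords.n
        weight += params.k2 * nq * (index.avdl - dl) / (index.avdl + dl)
    return ScoredPassage(passage_idx, weight, keyword_tf)


def search(
    index: CollectionIndex,
    keywords: KeywordSequence,
    params: BM25Params = BM25Params(),
    relinfo: RelevanceInfo = RelevanceInfo(),
    n_out: int = 1000,
    label: str = "termassoc",
) -> list[RunEntry]:
    """Top-``n_out`` passages containing at least one query keyword."""
    if n_out < 1:
        raise ValueError("n_out must be >= 1")
    candidates: set[int] = set()
    for kw in keywords.keywords:
        for idx, _tf in index.postings.get(kw, ()):
            candidates.add(idx)
    scored = [score_passage(i, keywords, index, params, relinfo) for i in sorted(candidates)]
    scored.sort(
        key=lambda sp: (
            -sp.weight,
            index.passages[sp.passage_idx].doc_id,
            index.passages[sp.passage_idx].offset,
        )
    )
    entries: list[RunEntry] = []
    for rank, sp in enumerate(scored[:n_out], 1):
        p = index.passages[sp.passage_idx]
        entries.append(
            RunEntry(keywords.topic_id, p.doc_id, rank, sp.weight, p.offset, p.length, label)
        )
    return entries


def generate_term_file(
    run: list[RunEntry],
    keywords: KeywordSequence,
    index: CollectionIndex,
) -> list[TermFileEntry]:
    """One entry per run entry in rank order: which query stems the passage holds."""
    by_location = {
        (p.doc_id, p.offset, p.length): p for p in index.passages
    }
    entries: list[TermFileEntry] = []
    for e in sorted(run, key=lambda e: e.rank):
        passage = by_location.get((e.doc_id, e.offset, e.length))
        if passage is None:
            raise KeyError(
                f"run entry rank {e.rank} references unindexed passage "
                f"({e.doc_id}, {e.offset}, {e.length})"
            )
        found = frozenset(kw for kw in keywords.keywords if passage.stems.get(kw, 0) >= 1)
        entries.append(TermFileEntry(keywords.topic_id, e.rank, keywords.n, found))
    return entries
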