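"""Passage extraction at three granularities plus collection statistics.

A *passage* is the indexing and retrieval unit: a contiguous character span
of a document together with the multiset of stems derived from exactly that
span. Three extraction granularities are supported:

* ``sentence`` — consecutive disjoint groups of up to 3 sentences within
  each paragraph;
* ``paragraph`` — one passage per paragraph span;
* ``word`` — fixed-size overlapping token windows (window ``W`` tokens,
  stride ``S``), character offsets snapped to token boundaries. This is a
  fixed-window stand-in for dynamic-window extraction and is flagged as an
  approximation in the docs.

Tokenization is shared with query processing: lowercase, split on
non-alphanumeric runs, Porter-stem each token.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

from .io import DocumentRecord
from .stemming import stem

_TOKEN = re.compile(r"[0-9a-zA-Z]+")
_SENT_END = re.compile(r"[.!?](?=\s|$)")


def tokenize(text: str) -> list[str]:
    """Lowercase alphanumeric tokens, Porter-stemmed."""
    return [stem(t.lower()) for t in _TOKEN.findall(text)]


def token_spans(text: str) -> list[tuple[int, int]]:
    """(start, end) character spans of the raw tokens, in order."""
    return [(m.start(), m.end()) for m in _TOKEN.finditer(text)]


@dataclass(frozen=True)
class Passage:
    doc_id: str
    offset: int
    length: int
    stems: Counter = field(compare=False)

    @property
    def dl(self) -> int:
        return sum(self.stems.values())


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Sentence spans covering the non-whitespace extent of *text*.

    A sentence ends at '.', '!' or '?' followed by whitespace or end of
    text; trailing material without a terminator forms a final sentence.
    Returned spans are trimmed of surrounding whitespace.
    """
    spans: list[tuple[int, int]] = []
    start = 0
    for m in _SENT_END.finditer(text):
        end = m.end()
        piece = text[start:end]
        lstrip = len(piece) - len(piece.lstrip())
        if piece.strip():
            spans.append((start + lstrip, end - start - lstrip))
        start = end
    piece = text[start:]
    if piece.strip():
        lstrip = len(piece) - len(piece.lstrip())
        rstrip = len(piece) - len(piece.rstrip())
        spans.append((start + lstrip, len(piece) - lstrip - rstrip))
    return spans


def _make_passage(doc: DocumentRecord, offset: int, length: int) -> Passage:
    chunk = doc.text[offset : offset + length]
    return Passage(doc.doc_id, offset, length, Counter(tokenize(chunk)))


def extract_passages(
    doc: DocumentRecord,
    granularity: str = "paragraph",
    max_sentences: int = 3,
    window: int = 35,
    stride: int = 17,
) -> list[Passage]:
    if granularity == "paragraph":
        return [_make_passage(doc, off, ln) for off, ln in doc.paragraph_spans]

    if granularity == "sentence":
        passages: list[Passage] = []
        for off, ln in doc.paragraph_spans:
            para = doc.text[off : off + ln]
            sents = split_sentences(para)
            for i in range(0, len(sents), max_sentences):
                group = sents[i : i + max_sentences]
                start = group[0][0]
                end = group[-1][0] + group[-1][1]
                passages.append(_make_passage(doc, off + start, end - start))
        return passages

    if granularity == "word":
        if window < 1 or stride < 1 or stride > window:
            raise ValueError("word windows need window >= 1 and 1 <= stride <= window")
        passages = []
        for off, ln in doc.paragraph_spans:
            para = doc.text[off : off + ln]
            spans = token_spans(para)
            if not spans:
                continue
            prev_range: tuple[int, int] | None = None
            for start_tok in range(0, len(spans), stride):
                end_tok = min(start_tok + window, len(spans))
                if prev_range is not None and start_tok >= prev_range[0] and end_tok <= prev_range[1]:
                    continue  # final short window fully inside the previous one
                char_start = spans[start_tok][0]
                char_end = spans[end_tok - 1][1]
                passages.append(_make_passage(doc, off + char_start, char_end - char_start))
                prev_range = (start_tok, end_tok)
                if end_tok == len(spans):
                    break
        return passages

    raise ValueError(f"unknown granularity {granularity!r}")


@dataclass(frozen=True)
class CollectionIndex:
    """Inverted index plus the collection statistics BM25 needs."""

    passages: tuple[Passage, ...]
    dl: tuple[int, ...]
    avdl: float
    df: dict[str, int]
    postings: dict[str, tuple[tuple[int, int], ...]]  # stem -> ((passage_idx, tf), ...)

    @property
    def n_passages(self) -> int:
        return len(self.passages)


def build_index(passages: list[Passage]) -> CollectionIndex:
    if not passages:
        raise ValueError("cannot index zero passages")
    dl = tuple(p.dl for p in passages)
    postings: dict[str, list[tuple[int, int]]] = {}
    for idx, p in enumerate(passages):
        for s, tf in p.stems.items():
            postings.setdefault(s, []).append((idx, tf))
    frozen = {s: tuple(pl) for s, pl in postings.items()}
    df = {s: len(pl) for s, pl in frozen.items()}
    return CollectionIndex(
        passages=tuple(passages),
        dl=dl,
        avdl=sum(dl) / len(dl),
        df=df,
        postings=frozen,
    )


def index_corpus(docs: list[DocumentRecord], granularity: str = "paragraph", **kw) -> CollectionIndex:
    passages: list[Passage] = []
    for doc in docs:
        passages.extend(extract_passages(doc, granularity, **kw))
    return build_index(passages)
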