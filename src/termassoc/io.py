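"""File formats used by the retrieval pipeline.

Five artefact kinds are read and/or written here:

* corpora — either one document per file with ``<p>``/``</p>`` paragraph
  markup (``html_p``) or one JSON object per line (``plain_jsonl``);
* topic files — one topic per line: id, whitespace, free-text description;
* run files — 7 tab-separated columns (topic, document, rank, weight,
  character offset, length, run label), the retrieval-result exchange
  format;
* term files — per retrieved passage, which query stems it contains;
* gold-standard files — judged relevant character spans as TSV
  (topic, document, offset, length).

Offsets everywhere are 0-based character indices into the tag-stripped
document text; spans are half-open ``[offset, offset + length)``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


class FormatError(ValueError):
    """A file does not conform to its expected layout."""


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DocumentRecord:
    doc_id: str
    text: str
    paragraph_spans: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_end = 0
        for offset, length in self.paragraph_spans:
            if length <= 0 or offset < 0 or offset + length > len(self.text):
                raise ValueError(
                    f"paragraph span ({offset},{length}) outside document "
                    f"{self.doc_id!r} of length {len(self.text)}"
                )
            if offset < prev_end:
                raise ValueError(
                    f"overlapping/unordered paragraph spans in {self.doc_id!r}"
                )
            prev_end = offset + length


@dataclass(frozen=True)
class TopicRecord:
    topic_id: str
    description: str

    def __post_init__(self) -> None:
        if not self.description.strip():
            raise ValueError(f"topic {self.topic_id!r} has empty description")


@dataclass(frozen=True)
class RunEntry:
    topic_id: str
    doc_id: str
    rank: int
    weight: float
    offset: int
    length: int
    label: str

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be positive")
        if self.length <= 0:
            raise ValueError("length must be positive")
        if self.offset < 0:
            raise ValueError("offset must be non-negative")


@dataclass(frozen=True)
class GoldSpan:
    topic_id: str
    doc_id: str
    offset: int
    length: int

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ValueError("gold span offset must be non-negative")
        if self.length <= 0:
            raise ValueError("gold span length must be positive")


@dataclass(frozen=True)
class TermFileEntry:
    topic_id: str
    passage_rank: int
    n_total: int
    found_stems: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(self.found_stems) > self.n_total:
            raise ValueError("more stems found than total query keywords")


# ---------------------------------------------------------------------------
# corpus
# ---------------------------------------------------------------------------

_P_TAG = re.compile(r"</?p\s*>", re.IGNORECASE)


def _parse_p_markup(raw: str, doc_id: str) -> tuple[str, tuple[tuple[int, int], ...]]:
    """Strip <p>/</p> tags; return clean text plus paragraph-content spans.

    A document without any tags keeps its whole text as a single span.
    """
    tags = list(_P_TAG.finditer(raw))
    if not tags:
        return raw, (((0, len(raw)),) if raw else tuple())
    text_parts: list[str] = []
    spans: list[tuple[int, int]] = []
    pos = 0  # position in raw
    out = 0  # position in stripped text
    open_at: int | None = None
    for m in tags:
        chunk = raw[pos : m.start()]
        text_parts.append(chunk)
        out += len(chunk)
        is_open = not m.group(0).startswith("</")
        if is_open:
            if open_at is not None:
                raise FormatError(f"nested <p> in document {doc_id!r}")
            open_at = out
        else:
            if open_at is None:
                raise FormatError(f"unmatched </p> in document {doc_id!r}")
            if out > open_at:
                spans.append((open_at, out - open_at))
            open_at = None
        pos = m.end()
    if open_at is not None:
        raise FormatError(f"unclosed <p> in document {doc_id!r}")
    chunk = raw[pos:]
    text_parts.append(chunk)
    return "".join(text_parts), tuple(spans)


def read_corpus(path: str | Path, dialect: str = "html_p") -> list[DocumentRecord]:
    """Read a corpus.

    ``html_p``: *path* is a file (one document, doc_id = file stem) or a
    directory of such files. ``plain_jsonl``: one JSON object per line with
    keys ``doc_id`` and ``text``; ``<p>`` markup inside the text is honoured
    the same way.
    """
    path = Path(path)
    docs: list[DocumentRecord] = []
    if dialect == "html_p":
        files = sorted(path.iterdir()) if path.is_dir() else [path]
        for f in files:
            raw = f.read_text(encoding="utf-8")
            if not raw:
                continue
            text, spans = _parse_p_markup(raw, f.stem)
            docs.append(DocumentRecord(f.stem, text, spans))
    elif dialect == "plain_jsonl":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                try:
                    obj = json.loads(line)
                    doc_id, raw = str(obj["doc_id"]), obj["text"]
                except (json.JSONDecodeError, KeyError, TypeError) as exc:
                    raise FormatError(f"{path}:{lineno}: bad corpus line") from exc
                text, spans = _parse_p_markup(raw, doc_id)
                docs.append(DocumentRecord(doc_id, text, spans))
    else:
        raise ValueError(f"unknown corpus dialect {dialect!r}")
    return docs


def write_corpus_jsonl(docs: Iterable[DocumentRecord], path: str | Path) -> None:
    """Write documents as JSONL, re-inserting <p> markup around paragraphs."""
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            pieces: list[str] = []
            pos = 0
            for offset, length in doc.paragraph_spans:
                pieces.append(doc.text[pos:offset])
                pieces.append("<p>" + doc.text[offset : offset + length] + "</p>")
                pos = offset + length
            pieces.append(doc.text[pos:])
            fh.write(json.dumps({"doc_id": doc.doc_id, "text": "".join(pieces)}) + "\n")


# ---------------------------------------------------------------------------
# topics
# ---------------------------------------------------------------------------

def read_topics(path: str | Path) -> list[TopicRecord]:
    topics: list[TopicRecord] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split(None, 1)
            if len(parts) < 2 or not parts[1].strip():
                raise FormatError(f"{path}:{lineno}: topic line needs id and description")
            topic_id, description = parts
            if topic_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate topic id {topic_id!r}")
            seen.add(topic_id)
            topics.append(TopicRecord(topic_id, description))
    return topics


def write_topics(topics: Iterable[TopicRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in topics:
            fh.write(f"{t.topic_id} {t.description}\n")


# ---------------------------------------------------------------------------
# run files
# ---------------------------------------------------------------------------

def validate_run(entries: Sequence[RunEntry], require_monotone_weights: bool = False) -> None:
    """Check per-topic rank consecutiveness (and optionally weight order)."""
    by_topic: dict[str, list[RunEntry]] = {}
    for e in entries:
        by_topic.setdefault(e.topic_id, []).append(e)
    for topic_id, group in by_topic.items():
        ranks = sorted(e.rank for e in group)
        if ranks != list(range(1, len(group) + 1)):
            raise FormatError(f"topic {topic_id!r}: ranks not consecutive 1..{len(group)}")
        if require_monotone_weights:
            ordered = sorted(group, key=lambda e: e.rank)
            for a, b in zip(ordered, ordered[1:]):
                if b.weight > a.weight + 1e-12:
                    raise FormatError(f"topic {topic_id!r}: weights increase with rank")


def _format_weight(w: float) -> str:
    s = repr(float(w))
    return s[:-2] if s.endswith(".0") else s


def write_run(entries: Sequence[RunEntry], path: str | Path) -> None:
    validate_run(entries)
    with open(path, "w", encoding="utf-8") as fh:
        for e in entries:
            fh.write(
                f"{e.topic_id}\t{e.doc_id}\t{e.rank}\t{_format_weight(e.weight)}"
                f"\t{e.offset}\t{e.length}\t{e.label}\n"
            )


def read_run(path: str | Path) -> list[RunEntry]:
    entries: list[RunEntry] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            cols = line.split()
            if len(cols) != 7:
                raise FormatError(f"{path}:{lineno}: expected 7 columns, got {len(cols)}")
            try:
                entries.append(
                    RunEntry(cols[0], cols[1], int(cols[2]), float(cols[3]),
                             int(cols[4]), int(cols[5]), cols[6])
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    validate_run(entries)
    return entries


# ---------------------------------------------------------------------------
# term files
# ---------------------------------------------------------------------------

_TERM_HEADER = re.compile(r"^Topic #(\S+)\s*$")
_TERM_LINE = re.compile(
    r"^passage #(\d+): (\d+) of the (\d+) terms was found >>(.*)$"
)


def write_term_file(entries: Sequence[TermFileEntry], path: str | Path) -> None:
    """Write entries grouped under per-topic headers, stems sorted."""
    with open(path, "w", encoding="utf-8") as fh:
        current: str | None = None
        for e in entries:
            if e.topic_id != current:
                fh.write(f"Topic #{e.topic_id}\n")
                current = e.topic_id
            stems = " ".join(sorted(e.found_stems))
            fh.write(
                f"passage #{e.passage_rank}: {len(e.found_stems)} of the "
                f"{e.n_total} terms was found >>{stems}\n"
            )


def read_term_file(path: str | Path) -> list[TermFileEntry]:
    entries: list[TermFileEntry] = []
    topic: str | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            header = _TERM_HEADER.match(line)
            if header:
                topic = header.group(1)
                continue
            m = _TERM_LINE.match(line)
            if m is None:
                raise FormatError(f"{path}:{lineno}: unrecognised term-file line")
            if topic is None:
                raise FormatError(f"{path}:{lineno}: passage line before any Topic header")
            rank, found, total, stems_raw = m.groups()
            stems = frozenset(stems_raw.split())
            if int(found) != len(stems):
                raise FormatError(
                    f"{path}:{lineno}: claims {found} stems but lists {len(stems)}"
                )
            entries.append(TermFileEntry(topic, int(rank), int(total), stems))
    return entries


# ---------------------------------------------------------------------------
# gold standard
# ---------------------------------------------------------------------------

def read_gold(path: str | Path) -> list[GoldSpan]:
    spans: list[GoldSpan] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            cols = line.split()
            if len(cols) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            try:
                spans.append(GoldSpan(cols[0], cols[1], int(cols[2]), int(cols[3])))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return spans


def write_gold(spans: Iterable[GoldSpan], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in spans:
            fh.write(f"{s.topic_id}\t{s.doc_id}\t{s.offset}\t{s.length}\n")
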