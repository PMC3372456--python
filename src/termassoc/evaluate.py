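"""TREC-Genomics style evaluation: document, passage and passage2 MAP.

* **document AP** — standard average precision over documents. Run entries
  are mapped to documents, repeats after a document's first retrieval are
  ignored, precision is recorded at each first retrieval of a relevant
  document, and the precision sum is divided by the number of relevant
  documents.

* **passage AP** — character-based. Walking the run in rank order,
  cumulative nominated characters and cumulative gold-overlapping
  characters are accumulated; at every rank whose passage overlaps at
  least one gold character, cumulative_overlap / cumulative_nominated is
  recorded. The sum of recorded precisions is divided by the topic's gold
  span count, so unretrieved gold passages contribute zero. A gold
  character is credited at most once in the numerator even if nominated
  repeatedly; the denominator counts every nomination.

* **passage2 AP** — every character is a mini relevance-judged document.
  The run expands into a stream of characters in published (rank, then
  in-passage) order; characters already emitted for the same document are
  dropped (first emission wins), each character is relevant iff inside a
  gold span, and standard AP is taken over the stream with total relevant
  equal to the topic's distinct gold character count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import GoldSpan, RunEntry


@dataclass
class GoldIndex:
    """Gold spans grouped per topic and per (topic, doc), with totals."""

    spans_by_topic_doc: dict[tuple[str, str], list[GoldSpan]] = field(default_factory=dict)
    relevant_docs: dict[str, set[str]] = field(default_factory=dict)
    span_count: dict[str, int] = field(default_factory=dict)
    char_count: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_spans(cls, spans: list[GoldSpan]) -> "GoldIndex":
        idx = cls()
        per_topic_doc_chars: dict[tuple[str, str], set[int]] = {}
        for s in spans:
            idx.spans_by_topic_doc.setdefault((s.topic_id, s.doc_id), []).append(s)
            idx.relevant_docs.setdefault(s.topic_id, set()).add(s.doc_id)
            idx.span_count[s.topic_id] = idx.span_count.get(s.topic_id, 0) + 1
            per_topic_doc_chars.setdefault((s.topic_id, s.doc_id), set()).update(
                range(s.offset, s.offset + s.length)
            )
        for (topic, _doc), chars in per_topic_doc_chars.items():
            idx.char_count[topic] = idx.char_count.get(topic, 0) + len(chars)
        return idx

    @property
    def topics(self) -> set[str]:
        return set(self.relevant_docs)


def _gold_mask(gold: GoldIndex, topic: str, doc: str, size: int) -> np.ndarray:
    mask = np.zeros(size, dtype=bool)
    for s in gold.spans_by_topic_doc.get((topic, doc), ()):
        mask[s.offset : min(s.offset + s.length, size)] = True
    return mask


def _doc_arrays(run: list[RunEntry], gold: GoldIndex, topic: str):
    """Per-doc gold mask + emitted mask sized to cover run and gold extents."""
    size: dict[str, int] = {}
    for e in run:
        size[e.doc_id] = max(size.get(e.doc_id, 0), e.offset + e.length)
    for (t, d), spans in gold.spans_by_topic_doc.items():
        if t == topic:
            size[d] = max(size.get(d, 0), max(s.offset + s.length for s in spans))
    return {
        d: (_gold_mask(gold, topic, d, n), np.zeros(n, dtype=bool)) for d, n in size.items()
    }


def document_ap(run: list[RunEntry], relevant_docs: set[str]) -> float:
    if not relevant_docs:
        raise ValueError("document AP undefined with an empty relevant set")
    seen: set[str] = set()
    hits = 0
    precisions: list[float] = []
    for e in sorted(run, key=lambda e: e.rank):
        if e.doc_id in seen:
            continue
        seen.add(e.doc_id)
        if e.doc_id in relevant_docs:
            hits += 1
            precisions.append(hits / len(seen))
    return sum(precisions) / len(relevant_docs)


def passage_ap(run: list[RunEntry], gold: GoldIndex, topic: str) -> float:
    n_gold_spans = gold.span_count.get(topic, 0)
    if n_gold_spans == 0:
        raise ValueError(f"no gold spans for topic {topic!r}")
    arrays = _doc_arrays(run, gold, topic)
    nominated = 0
    overlap = 0
    precisions: list[float] = []
    for e in sorted(run, key=lambda e: e.rank):
        gold_mask, credited = arrays[e.doc_id]
        sl = slice(e.offset, e.offset + e.length)
        nominated += e.length
        relevant_here = gold_mask[sl]
        if relevant_here.any():
            new_credit = relevant_here & ~credited[sl]
            overlap += int(new_credit.sum())
            credited[sl] |= relevant_here
            precisions.append(overlap / nominated)
    return sum(precisions) / n_gold_spans


def passage2_ap(run: list[RunEntry], gold: GoldIndex, topic: str) -> float:
    total_relevant = gold.char_count.get(topic, 0)
    if total_relevant == 0:
        raise ValueError(f"no gold characters for topic {topic!r}")
    arrays = _doc_arrays(run, gold, topic)
    emitted = 0
    rel_seen = 0
    ap_sum = 0.0
    for e in sorted(run, key=lambda e: e.rank):
        gold_mask, emitted_mask = arrays[e.doc_id]
        for pos in range(e.offset, e.offset + e.length):
            if emitted_mask[pos]:
                continue
            emitted_mask[pos] = True
            emitted += 1
            if gold_mask[pos]:
                rel_seen += 1
                ap_sum += rel_seen / emitted
    return ap_sum / total_relevant


LEVELS = ("document", "passage", "passage2")


@dataclass(frozen=True)
class EvalReport:
    """Per-topic APs and their mean (MAP) per evaluation level."""

    per_topic: dict[str, dict[str, float]]  # level -> topic -> AP
    map: dict[str, float]                   # level -> MAP

    def __str__(self) -> str:
        lines = ["level\ttopic\tAP"]
        for level, topics in self.per_topic.items():
            for t, ap in sorted(topics.items()):
                lines.append(f"{level}\t{t}\t{ap:.4f}")
        for level, m in self.map.items():
            lines.append(f"{level}\tMAP\t{m:.4f}")
        return "\n".join(lines)


def evaluate_run(
    run: list[RunEntry],
    gold: list[GoldSpan] | GoldIndex,
    levels: tuple[str, ...] = LEVELS,
) -> EvalReport:
    """Evaluate a (possibly multi-topic) run at the requested levels.

    Run topics absent from the gold standard are skipped with a warning.
    """
    for level in levels:
        if level not in LEVELS:
            raise ValueError(f"unknown evaluation level {level!r}")
    gold_index = gold if isinstance(gold, GoldIndex) else GoldIndex.from_spans(gold)
    by_topic: dict[str, list[RunEntry]] = {}
    for e in run:
        by_topic.setdefault(e.topic_id, []).append(e)
    per_topic: dict[str, dict[str, float]] = {level: {} for level in levels}
    for topic in sorted(by_topic):
        if topic not in gold_index.topics:
            warnings.warn(f"topic {topic!r} has no gold judgements; skipped")
            continue
        topic_run = by_topic[topic]
        for level in levels:
            if level == "document":
                ap = document_ap(topic_run, gold_index.relevant_docs[topic])
            elif level == "passage":
                ap = passage_ap(topic_run, gold_index, topic)
            else:
                ap = passage2_ap(topic_run, gold_index, topic)
            per_topic[level][topic] = ap
    maps = {
        level: (sum(v.values()) / len(v) if v else float("nan"))
        for level, v in per_topic.items()
    }
    return EvalReport(per_topic=per_topic, map=maps)


def compare_reports(baseline: EvalReport, improved: EvalReport) -> dict[str, float | None]:
    """Relative improvement 100·(new-old)/old per level; None when old is 0."""
    if set(baseline.map) != set(improved.map):
        raise ValueError("reports cover different levels")
    for level in baseline.map:
        if set(baseline.per_topic[level]) != set(improved.per_topic[level]):
            raise ValueError(f"reports cover different topics at level {level!r}")
    out: dict[str, float | None] = {}
    for level, old in baseline.map.items():
        new = improved.map[level]
        out[level] = None if old == 0 else 100.0 * (new - old) / old
    return out
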