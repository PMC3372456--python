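"""End-to-end orchestration: index -> search -> associations -> re-rank -> eval.

`run_topic` is the in-memory engine for a single topic; `run_pipeline`
is the file-based front end that reads a corpus/topics/gold triple,
processes every topic, and writes all artefacts (baseline run, term file,
association ranking, factor-model re-ranked run, GSP re-ranked run,
evaluation report, manifest) into an output directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as tio
from .associations import (
    build_observation_matrix,
    fit_factor_model,
    rank_associations,
    score_associations,
)
from .bm25 import PARAM_GRID, BM25Params, generate_term_file, search
from .evaluate import LEVELS, EvalReport, compare_reports, evaluate_run
from .gsp import (
    build_sequences,
    candidate_supports,
    gsp_mine,
    gsp_rerank,
    minimum_support,
)
from .passages import CollectionIndex, index_corpus
from .query import DEFAULT_STOPWORDS, KeywordSequence, extract_keywords
from .rerank import presence_from_term_file, recursive_rerank

logger = logging.getLogger("termassoc")

GRANULARITIES = ("sentence", "paragraph", "word")


@dataclass(frozen=True)
class PipelineConfig:
    granularity: str = "paragraph"
    params: BM25Params = field(default_factory=BM25Params)
    n_out: int = 1000
    k: int = 10
    factor_rule: str | int | tuple = "mp"
    label: str = "termassoc"
    levels: tuple[str, ...] = LEVELS

    def __post_init__(self) -> None:
        if self.granularity not in GRANULARITIES:
            raise ValueError(
                f"unknown granularity {self.granularity!r}; expected one of {GRANULARITIES}"
            )
        if self.n_out < 1 or self.k < 0:
            raise ValueError("n_out must be >= 1 and k >= 0")


def expand_preset(name: str) -> list[BM25Params]:
    """Named parameter presets; "trec-grid" is the five standard (k1, b) pairs."""
    if name == "trec-grid":
        return [BM25Params(k1=k1, b=b) for k1, b in PARAM_GRID]
    raise ValueError(f"unknown preset {name!r}")


@dataclass
class TopicResult:
    keywords: KeywordSequence
    baseline: list[tio.RunEntry]
    term_file: list[tio.TermFileEntry]
    ranking: list  # AssociationScore, best first
    reranked: list[tio.RunEntry]
    gsp_frequent: dict
    gsp_min_support: float
    gsp_reranked: list[tio.RunEntry]


def run_topic(
    topic: tio.TopicRecord,
    index: CollectionIndex,
    config: PipelineConfig = PipelineConfig(),
    stopwords=DEFAULT_STOPWORDS,
) -> TopicResult:
    keywords = extract_keywords(topic, stopwords)
    baseline = search(index, keywords, config.params, n_out=config.n_out, label=config.label)
    term_file = generate_term_file(baseline, keywords, index)
    logger.info(
        "topic %s: %d keywords, %d passages retrieved", topic.topic_id, keywords.n, len(baseline)
    )

    matrix = build_observation_matrix(term_file, keywords)
    model = fit_factor_model(matrix, config.factor_rule)
    scores = score_associations(matrix, model)
    ranking = rank_associations(scores, k=config.k) if config.k else []
    presence = presence_from_term_file(term_file, ranking, keywords)
    reranked = recursive_rerank(
        baseline, presence, k=config.k, label=config.label + "-ta"
    )
    logger.info(
        "topic %s: %d associations, %d factors retained", topic.topic_id, len(scores), model.m
    )

    sequences = build_sequences(baseline, term_file)
    supports = candidate_supports(sequences, keywords, max_len=3)
    min_sup = minimum_support(list(supports.values()))
    frequent = gsp_mine(sequences, keywords, min_sup, max_len=3)
    gsp_run = gsp_rerank(
        baseline, sequences, frequent, keywords, k=config.k, label=config.label + "-gsp"
    )
    return TopicResult(
        keywords=keywords,
        baseline=baseline,
        term_file=term_file,
        ranking=ranking,
        reranked=reranked,
        gsp_frequent=frequent,
        gsp_min_support=min_sup,
        gsp_reranked=gsp_run,
    )


@dataclass
class PipelineResult:
    per_topic: dict[str, TopicResult]
    baseline_report: EvalReport | None
    rerank_report: EvalReport | None
    gsp_report: EvalReport | None
    improvement: dict | None


def run_corpus(
    docs: list[tio.DocumentRecord],
    topics: list[tio.TopicRecord],
    gold: list[tio.GoldSpan] | None = None,
    config: PipelineConfig = PipelineConfig(),
    stopwords=DEFAULT_STOPWORDS,
) -> PipelineResult:
    index = index_corpus(docs, config.granularity)
    per_topic = {t.topic_id: run_topic(t, index, config, stopwords) for t in topics}
    baseline = [e for r in per_topic.values() for e in r.baseline]
    reranked = [e for r in per_topic.values() for e in r.reranked]
    gsp_run = [e for r in per_topic.values() for e in r.gsp_reranked]
    if gold:
        base_rep = evaluate_run(baseline, gold, config.levels)
        ta_rep = evaluate_run(reranked, gold, config.levels)
        gsp_rep = evaluate_run(gsp_run, gold, config.levels)
        improvement = compare_reports(base_rep, ta_rep)
    else:
        base_rep = ta_rep = gsp_rep = improvement = None
    return PipelineResult(per_topic, base_rep, ta_rep, gsp_rep, improvement)


def run_pipeline(
    corpus_path: str | Path,
    topics_path: str | Path,
    out_dir: str | Path,
    gold_path: str | Path | None = None,
    corpus_dialect: str = "plain_jsonl",
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """File-based pipeline; writes all artefacts plus a manifest to *out_dir*."""
    corpus_path, topics_path = Path(corpus_path), Path(topics_path)
    for p in (corpus_path, topics_path) + ((Path(gold_path),) if gold_path else ()):
        if not p.exists():
            raise FileNotFoundError(f"pipeline input missing: {p}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    docs = tio.read_corpus(corpus_path, corpus_dialect)
    topics = tio.read_topics(topics_path)
    gold = tio.read_gold(gold_path) if gold_path else None
    result = run_corpus(docs, topics, gold, config)

    all_entries = lambda attr: [e for r in result.per_topic.values() for e in getattr(r, attr)]
    tio.write_run(all_entries("baseline"), out / "baseline.run")
    tio.write_run(all_entries("reranked"), out / "rerank-ta.run")
    tio.write_run(all_entries("gsp_reranked"), out / "rerank-gsp.run")
    tio.write_term_file(all_entries("term_file"), out / "termfile.txt")
    with open(out / "ranking.tsv", "w", encoding="utf-8") as fh:
        fh.write("topic\tterm_association\tterm_count\tcommunality_pct\n")
        for topic_id, r in result.per_topic.items():
            for s in r.ranking:
                fh.write(
                    f"{topic_id}\t{s.term.display(r.keywords)}\t{s.count}"
                    f"\t{s.communality_pct:.1f}\n"
                )
    if result.baseline_report is not None:
        with open(out / "eval.tsv", "w", encoding="utf-8") as fh:
            for name, rep in (
                ("baseline", result.baseline_report),
                ("term-association", result.rerank_report),
                ("gsp", result.gsp_report),
            ):
                fh.write(f"# {name}\n{rep}\n")
    manifest = {
        "granularity": config.granularity,
        "bm25": {"k1": config.params.k1, "b": config.params.b,
                 "k2": config.params.k2, "k3": config.params.k3},
        "n_out": config.n_out,
        "k": config.k,
        "factor_rule": str(config.factor_rule),
        "inputs": {"corpus": str(corpus_path), "topics": str(topics_path),
                   "gold": str(gold_path) if gold_path else None},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result
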