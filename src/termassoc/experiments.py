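"""Replicated synthetic experiments used for model validation.

The central check: on collections where one planted bigram's keywords
co-occur through a strong latent factor, the factor model should put that
bigram near the top of the communality ranking, and recursive re-ranking
with the top associations should not hurt (usually helps) document-level
MAP relative to the BM25 baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

from .associations import (
    build_observation_matrix,
    fit_factor_model,
    rank_associations,
    score_associations,
)
from .bm25 import generate_term_file, search
from .evaluate import GoldIndex, document_ap
from .passages import index_corpus
from .pipeline import PipelineConfig
from .query import extract_keywords
from .rerank import presence_from_term_file, recursive_rerank
from .synthetic import generate_collection, planted_spec


@dataclass(frozen=True)
class RecoveryResult:
    seed: int
    bigram_rank: int           # 1-based position of the planted bigram
    baseline_doc_ap: float
    reranked_doc_ap: float

    @property
    def bigram_in_top3(self) -> bool:
        return self.bigram_rank <= 3

    @property
    def rerank_not_worse(self) -> bool:
        return self.reranked_doc_ap >= self.baseline_doc_ap - 1e-12


def planted_bigram_replicate(
    seed: int,
    loading: float = 2.0,
    n_out: int = 500,
    config: PipelineConfig | None = None,
) -> RecoveryResult:
    """One full-pipeline replicate on a collection with a planted bigram."""
    cfg = config or PipelineConfig(n_out=n_out)
    spec = planted_spec(pair=(0, 1), loading=loading)
    coll = generate_collection(spec, seed)
    index = index_corpus(coll.corpus, cfg.granularity)
    keywords = extract_keywords(coll.topic)
    run = search(index, keywords, cfg.params, n_out=cfg.n_out)
    term_file = generate_term_file(run, keywords, index)

    matrix = build_observation_matrix(term_file, keywords)
    model = fit_factor_model(matrix, cfg.factor_rule)
    ranking_full = rank_associations(score_associations(matrix, model), k=len(matrix.terms))
    planted = tuple(coll.truth["planted_keyword_indices"])
    bigram_rank = next(
        pos for pos, s in enumerate(ranking_full, 1) if s.term.keyword_indices == planted
    )

    top_k = ranking_full[: cfg.k]
    presence = presence_from_term_file(term_file, top_k, keywords)
    reranked = recursive_rerank(run, presence, k=cfg.k)

    gold_index = GoldIndex.from_spans(list(coll.gold))
    relevant = gold_index.relevant_docs[coll.topic.topic_id]
    return RecoveryResult(
        seed=seed,
        bigram_rank=bigram_rank,
        baseline_doc_ap=document_ap(run, relevant),
        reranked_doc_ap=document_ap(reranked, relevant),
    )


@dataclass(frozen=True)
class RecoverySummary:
    results: tuple[RecoveryResult, ...]

    @property
    def top3_rate(self) -> float:
        return sum(r.bigram_in_top3 for r in self.results) / len(self.results)

    @property
    def improved_rate(self) -> float:
        return sum(r.rerank_not_worse for r in self.results) / len(self.results)

    @property
    def mean_baseline_map(self) -> float:
        return sum(r.baseline_doc_ap for r in self.results) / len(self.results)

    @property
    def mean_reranked_map(self) -> float:
        return sum(r.reranked_doc_ap for r in self.results) / len(self.results)


def planted_bigram_study(n_reps: int = 50, base_seed: int = 0, **kw) -> RecoverySummary:
    """Run *n_reps* seeded replicates; seeds are base_seed+1 .. base_seed+n_reps."""
    results = tuple(
        planted_bigram_replicate(base_seed + i, **kw) for i in range(1, n_reps + 1)
    )
    return RecoverySummary(results)
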