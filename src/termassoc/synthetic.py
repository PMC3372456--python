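"""Synthetic test collections with planted latent-factor keyword structure.

Each paragraph (the natural passage unit of the generated corpora) draws a
latent relevance factor f ~ N(0, 1). Query keyword i then appears in the
paragraph with probability logistic(alpha_i + lambda_i * f): alpha_i sets
the keyword's baseline presence log-odds, and lambda_i couples it to the
latent factor, so keywords with large loadings co-occur far more often
than independence predicts — exactly the correlation structure the factor
model is built to detect. Paragraphs whose f exceeds the
(1 - relevant_fraction) standard-normal quantile are *relevant*; their
exact character spans become the gold standard, so retrieval quality can
be scored at the document and character levels.

Keyword surface forms default to Porter-stable words (stem == surface) so
generator tests are decoupled from the stemmer. Everything is driven by a
single integer seed and is fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .io import DocumentRecord, GoldSpan, TopicRecord
from .stemming import stem

#: Porter-stable default keyword surface forms (stem(w) == w for each).
DEFAULT_KEYWORDS = ("alpha", "beta", "gamma", "delta")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one generated collection.

    Default marginals put each keyword in roughly a fifth of passages —
    the middle of the per-keyword passage-frequency spread seen in real
    retrieved term files, where topical terms appear in a few hundred of
    1000 passages and peripheral ones in well under a hundred.
    """

    n_docs: int = 160
    paragraphs_per_doc: int = 5
    sentences_per_paragraph: int = 3
    filler_vocab_size: int = 200
    keywords: tuple[str, ...] = DEFAULT_KEYWORDS
    alpha: tuple[float, ...] = (-1.4,) * len(DEFAULT_KEYWORDS)
    lam: tuple[float, ...] = (0.0,) * len(DEFAULT_KEYWORDS)
    relevant_fraction: float = 0.2
    words_per_sentence: int = 8
    topic_id: str = "900"

    def __post_init__(self) -> None:
        if len(self.keywords) < 2:
            raise ValueError("need at least 2 keywords")
        if len(self.alpha) != len(self.keywords) or len(self.lam) != len(self.keywords):
            raise ValueError("alpha and lam must match the keyword count")
        if not 0 < self.relevant_fraction < 1:
            raise ValueError("relevant_fraction must be in (0, 1)")

    @property
    def n_keywords(self) -> int:
        return len(self.keywords)


def planted_spec(
    pair: tuple[int, int] = (0, 1),
    loading: float = 2.0,
    planted_alpha: float = -0.8,
    **overrides,
) -> SyntheticSpec:
    """Spec with one planted bigram: both keywords load `loading` on the factor.

    The planted keywords also get a higher intercept than the background
    ones: topical terms are the frequent ones in first-round retrieved
    passages, while peripheral query terms stay rare. Keeping background
    joint counts moderate (neither near-zero nor dominant) is what lets
    the factor model separate the planted co-occurrence from the
    product-structure correlation every bigram shares with its component
    unigrams.
    """
    base = SyntheticSpec(**overrides)
    lam = [0.0] * base.n_keywords
    alpha = list(base.alpha)
    for i in pair:
        lam[i] = loading
        alpha[i] = planted_alpha
    return SyntheticSpec(**{**base.__dict__, "lam": tuple(lam), "alpha": tuple(alpha)})


@dataclass(frozen=True)
class SyntheticCollection:
    spec: SyntheticSpec
    corpus: tuple[DocumentRecord, ...]
    topic: TopicRecord
    gold: tuple[GoldSpan, ...]
    truth: dict = field(compare=False)


def _filler_vocab(spec: SyntheticSpec) -> list[str]:
    vocab = []
    i = 0
    while len(vocab) < spec.filler_vocab_size:
        word = "zz" + _base26(i)
        i += 1
        vocab.append(word)
    collisions = set(vocab) & set(spec.keywords)
    collisions |= {stem(w) for w in vocab} & {stem(k) for k in spec.keywords}
    if collisions:
        raise ValueError(f"filler vocabulary collides with keywords: {sorted(collisions)}")
    return vocab


def _base26(i: int) -> str:
    out = ""
    while True:
        out = chr(97 + i % 26) + out
        i //= 26
        if i == 0:
            return out


def generate_collection(spec: SyntheticSpec, seed: int) -> SyntheticCollection:
    """Deterministically generate corpus, topic and gold spans for *spec*."""
    rng = np.random.default_rng(seed)
    vocab = _filler_vocab(spec)
    alpha = np.asarray(spec.alpha)
    lam = np.asarray(spec.lam)
    threshold = norm.ppf(1.0 - spec.relevant_fraction)

    docs: list[DocumentRecord] = []
    gold: list[GoldSpan] = []
    relevant_flags: list[bool] = []
    factor_values: list[float] = []
    for d in range(spec.n_docs):
        doc_id = f"SD{d:04d}"
        parts: list[str] = []
        spans: list[tuple[int, int]] = []
        pos = 0
        for _p in range(spec.paragraphs_per_doc):
            f = float(rng.standard_normal())
            factor_values.append(f)
            probs = 1.0 / (1.0 + np.exp(-(alpha + lam * f)))
            present = [spec.keywords[i] for i in range(spec.n_keywords) if rng.random() < probs[i]]
            sentences: list[list[str]] = [
                list(rng.choice(vocab, size=spec.words_per_sentence))
                for _ in range(spec.sentences_per_paragraph)
            ]
            for kw in present:
                s = int(rng.integers(spec.sentences_per_paragraph))
                w = int(rng.integers(len(sentences[s]) + 1))
                sentences[s].insert(w, kw)
            para = " ".join(" ".join(s).capitalize() + "." for s in sentences)
            start = pos
            parts.append(para)
            spans.append((start, len(para)))
            pos += len(para)
            parts.append(" ")
            pos += 1
            relevant = f > threshold
            relevant_flags.append(relevant)
            if relevant:
                gold.append(GoldSpan(spec.topic_id, doc_id, start, len(para)))
        text = "".join(parts).rstrip()
        docs.append(DocumentRecord(doc_id, text, tuple(spans)))

    topic = TopicRecord(
        spec.topic_id, "what is the " + " ".join(spec.keywords) + " of this?"
    )
    planted = tuple(int(i) for i in np.nonzero(lam)[0])
    truth = {
        "planted_keyword_indices": planted,
        "n_relevant_passages": int(sum(relevant_flags)),
        "latent_threshold": float(threshold),
    }
    return SyntheticCollection(spec, tuple(docs), topic, tuple(gold), truth)


def make_gold(collection: SyntheticCollection) -> tuple[GoldSpan, ...]:
    """The gold spans of a generated collection (one per relevant passage)."""
    return collection.gold
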