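"""Query processing: topic description -> ordered keyword stem sequence.

The keyword sequence k1..kn drives everything downstream: its subsequences
are the candidate term associations, and its order fixes the canonical
enumeration order of those associations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from .io import TopicRecord
from .stemming import stem

# Compact English IR stopword list (classic van Rijsbergen-style selection).
# Configurable via the `stopwords` argument of extract_keywords.
DEFAULT_STOPWORDS = frozenset("""
a about above across after again against all almost alone along already also
although always am among an and another any anybody anyone anything anywhere
are area around as at be became because become becomes been before behind
being between both but by came can cannot case certain clearly come could did
differ different do does done down during each either enough even ever every
everybody everyone everything everywhere few find finds first for found from
further gave general get gets give given go goes gone got great had has have
having he her here herself him himself his how however i if importance
important in indeed interest into is it its itself just keep kept kind knew
know known large largely later least less let lets like likely long longer
made make making man many may me might more most mostly mr mrs much must my
myself necessary need needs never new next no nobody non nor not nothing now
nowhere of off often on once one only onto or other others our out over part
per perhaps put quite rather really right room said same saw say second see
seem seemed seeming seems several shall she should show showed shown side
since so some somebody someone something somewhere still such sure take than
that the their them then there therefore these they thing things think this
those though three through thus to together too toward turn two under until
up upon us use used uses very want wanted wants was way ways we well went
were what when where whether which while who whole whose why will with within
without would year yet you your yours
""".split())

_WORD = re.compile(r"[0-9a-zA-Z]+")


@dataclass(frozen=True)
class KeywordSequence:
    """Ordered unique query stems k1..kn, in first-appearance order."""

    topic_id: str
    keywords: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.keywords)

    def index_of(self, keyword: str) -> int:
        return self.keywords.index(keyword)


class EmptyQueryError(ValueError):
    """Every token of the description was a stopword."""


def extract_keywords(
    topic: TopicRecord,
    stopwords: frozenset[str] | set[str] = DEFAULT_STOPWORDS,
) -> KeywordSequence:
    """Tokenize, drop stopwords, Porter-stem, deduplicate keeping first position.

    Bracketed entity markers like ``[PROTEINS]`` contribute their inner
    token, since bracket characters are stripped by tokenization.
    """
    seen: set[str] = set()
    keywords: list[str] = []
    for token in _WORD.findall(topic.description):
        token = token.lower()
        if token in stopwords:
            continue
        s = stem(token)
        if s not in seen:
            seen.add(s)
            keywords.append(s)
    if not keywords:
        raise EmptyQueryError(
            f"topic {topic.topic_id!r}: all tokens removed as stopwords"
        )
    return KeywordSequence(topic.topic_id, tuple(keywords))


def load_stopwords(path: str | Path) -> frozenset[str]:
    """One stopword per whitespace-separated token, lowercased."""
    return frozenset(w.lower() for w in Path(path).read_text(encoding="utf-8").split())
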