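"""Recursive binary-partition re-ranking of a first-round run.

The ranked association list T'_1..T'_k drives a recursive split of the
result list: first into the passages containing T'_1 followed by those not
containing it; each part is then split the same way by T'_2, and so on
down to T'_k, yielding up to 2^k leaf bins whose odd (first) halves contain
the association at each level. Inside every leaf bin passages keep their
descending original-weight order; weights are never recomputed, only ranks
are reassigned 1..M. The whole procedure is therefore equivalent to a
stable sort by the key (-contains(T'_1), ..., -contains(T'_k), -weight),
which the tests exploit as an independent oracle.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .io import RunEntry


def recursive_rerank(
    run: Sequence[RunEntry],
    presence: Mapping[int, Sequence[bool]],
    k: int | None = None,
    label: str | None = None,
) -> list[RunEntry]:
    """Re-rank one topic's run by presence of the top-k associations.

    ``presence[rank]`` is the per-association containment vector of the run
    entry with that rank, ordered by association priority (best first). All
    vectors must cover every association considered; ``k`` defaults to the
    full vector length and is capped by it.
    """
    if not run:
        return []
    entries = sorted(run, key=lambda e: e.rank)
    vec_len: int | None = None
    for e in entries:
        if e.rank not in presence:
            raise KeyError(f"no association-presence vector for run entry rank {e.rank}")
        v = presence[e.rank]
        if vec_len is None:
            vec_len = len(v)
        elif len(v) != vec_len:
            raise ValueError("presence vectors have inconsistent lengths")
    assert vec_len is not None
    depth = vec_len if k is None else max(0, min(k, vec_len))

    # leaf bins are sorted by descending original weight (stable: equal
    # weights keep first-round rank order)
    def partition(block: list[RunEntry], level: int) -> list[RunEntry]:
        if level >= depth or len(block) <= 1:
            return sorted(block, key=lambda e: -e.weight)
        containing = [e for e in block if presence[e.rank][level]]
        rest = [e for e in block if not presence[e.rank][level]]
        return partition(containing, level + 1) + partition(rest, level + 1)

    reordered = partition(entries, 0)
    out_label = label if label is not None else entries[0].label
    return [
        RunEntry(e.topic_id, e.doc_id, new_rank, e.weight, e.offset, e.length, out_label)
        for new_rank, e in enumerate(reordered, 1)
    ]


def presence_from_term_file(entries, ranking, keywords) -> dict[int, tuple[bool, ...]]:
    """Containment vectors for a run, from its term file and a ranked association list.

    ``ranking`` is a sequence of AssociationScore (best first); containment
    reuses set semantics: an association is present iff every component
    stem is among the passage's found stems.
    """
    from .associations import association_present

    out: dict[int, tuple[bool, ...]] = {}
    for e in entries:
        out[e.passage_rank] = tuple(
            bool(association_present(s.term, e.found_stems, keywords)) for s in ranking
        )
    return out
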