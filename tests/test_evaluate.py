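"""Document, passage and passage2 average precision."""

import math

import pytest

from termassoc.evaluate import (
    GoldIndex,
    compare_reports,
    document_ap,
    evaluate_run,
    passage2_ap,
    passage_ap,
)
from termassoc.io import GoldSpan, RunEntry


def _entry(doc, rank, offset, length, topic="1", weight=None):
    return RunEntry(topic, doc, rank, weight if weight is not None else 100.0 - rank,
                    offset, length, "t")


class TestDocumentAP:
    def test_rel_nonrel_rel(self):
        run = [_entry("R1", 1, 0, 10), _entry("N", 2, 0, 10), _entry("R2", 3, 0, 10)]
        assert document_ap(run, {"R1", "R2"}) == pytest.approx(5 / 6)

    def test_no_relevant_retrieved(self):
        run = [_entry("N", 1, 0, 10)]
        assert document_ap(run, {"R"}) == 0.0

    def test_perfect_prefix(self):
        run = [_entry("R1", 1, 0, 10), _entry("R2", 2, 0, 10)]
        assert document_ap(run, {"R1", "R2"}) == 1.0

    def test_duplicate_docs_after_first_ignored(self):
        run = [
            _entry("R1", 1, 0, 10), _entry("R1", 2, 50, 10), _entry("R2", 3, 0, 10),
        ]
        # R2 is the 2nd distinct doc seen -> precision 2/2
        assert document_ap(run, {"R1", "R2"}) == 1.0

    def test_empty_relevant_set_rejected(self):
        with pytest.raises(ValueError):
            document_ap([], set())


class TestPassageAP:
    def test_exact_cover(self):
        gold = GoldIndex.from_spans([GoldSpan("1", "D", 100, 100)])
        run = [_entry("D", 1, 100, 100)]
        assert passage_ap(run, gold, "1") == 1.0

    def test_half_overlap_single_retrieval(self):
        # gold [100,200); retrieval D[150,250): 50 overlapping of 100 nominated
        gold = GoldIndex.from_spans([GoldSpan("1", "D", 100, 100)])
        run = [_entry("D", 1, 150, 100)]
        assert passage_ap(run, gold, "1") == pytest.approx(0.5, abs=1e-12)

    def test_zero_overlap(self):
        gold = GoldIndex.from_spans([GoldSpan("1", "D", 0, 10)])
        run = [_entry("D", 1, 500, 100)]
        assert passage_ap(run, gold, "1") == 0.0

    def test_unretrieved_gold_spans_lower_ap(self):
        gold = GoldIndex.from_spans(
            [GoldSpan("1", "D", 0, 10), GoldSpan("1", "E", 0, 10)]
        )
        run = [_entry("D", 1, 0, 10)]
        assert passage_ap(run, gold, "1") == pytest.approx(0.5)

    def test_gold_characters_credited_once(self):
        gold = GoldIndex.from_spans([GoldSpan("1", "D", 0, 10)])
        run = [_entry("D", 1, 0, 10), _entry("D", 2, 0, 10)]
        # rank1: 10/10; rank2 overlaps gold but adds no new credit: 10/20
        assert passage_ap(run, gold, "1") == pytest.approx((1.0 + 0.5) / 1)


class TestPassage2AP:
    def test_exact_cover(self):
        gold = GoldIndex.from_spans([GoldSpan("1", "D", 5, 10)])
        run = [_entry("D", 1, 5, 10)]
        assert passage2_ap(run, gold, "1") == 1.0

    def test_one_leading_irrelevant_character(self):
        # gold D[5,15); retrieved D[4,15): AP = (sum_{i=1..10} i/(i+1))/10
        gold = GoldIndex.from_spans([GoldSpan("1", "D", 5, 10)])
        run = [_entry("D", 1, 4, 11)]
        expected = sum(i / (i + 1) for i in range(1, 11)) / 10
        assert passage2_ap(run, gold, "1") == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.798, abs=5e-4)

    def test_zero_overlap(self):
        gold = GoldIndex.from_spans([GoldSpan("1", "D", 0, 5)])
        run = [_entry("D", 1, 100, 20)]
        assert passage2_ap(run, gold, "1") == 0.0

    def test_repeated_characters_not_reemitted(self):
        gold = GoldIndex.from_spans([GoldSpan("1", "D", 0, 10)])
        run = [_entry("D", 1, 0, 10), _entry("D", 2, 0, 10)]
        assert passage2_ap(run, gold, "1") == 1.0

    def test_promoting_gold_passage_never_decreases_ap(self):
        gold = GoldIndex.from_spans([GoldSpan("1", "D", 50, 20)])
        worse = [_entry("E", 1, 0, 30), _entry("D", 2, 50, 20)]
        better = [_entry("D", 1, 50, 20), _entry("E", 2, 0, 30)]
        assert passage2_ap(better, gold, "1") >= passage2_ap(worse, gold, "1")

    def test_single_char_passages_reduce_to_document_ap(self):
        # every passage one character, gold spans single characters: the
        # character stream IS a document ranking
        gold_spans = [GoldSpan("1", "D", 3, 1), GoldSpan("1", "D", 7, 1)]
        gold = GoldIndex.from_spans(gold_spans)
        run = [
            _entry("D", 1, 3, 1), _entry("D", 2, 5, 1), _entry("D", 3, 7, 1),
        ]
        pseudo_docs_relevant = {"D:3", "D:7"}
        pseudo_run = [
            RunEntry("1", f"{e.doc_id}:{e.offset}", e.rank, e.weight, 0, 1, "t")
            for e in run
        ]
        assert passage2_ap(run, gold, "1") == pytest.approx(
            document_ap(pseudo_run, pseudo_docs_relevant)
        )


class TestEvaluateRun:
    def _setup(self):
        gold = [GoldSpan("1", "D", 0, 10), GoldSpan("2", "E", 0, 10)]
        run = [
            _entry("D", 1, 0, 10, topic="1"),
            _entry("E", 1, 0, 10, topic="2"),
        ]
        return run, gold

    def test_perfect_run_all_levels_one(self):
        run, gold = self._setup()
        report = evaluate_run(run, gold)
        assert all(m == pytest.approx(1.0) for m in report.map.values())

    def test_map_is_mean_over_topics(self):
        gold = [GoldSpan("1", "D", 0, 10), GoldSpan("2", "E", 0, 10)]
        run = [
            _entry("D", 1, 0, 10, topic="1"),
            _entry("X", 1, 0, 10, topic="2"),  # miss
        ]
        report = evaluate_run(run, gold, levels=("document",))
        assert report.map["document"] == pytest.approx(0.5)

    def test_unjudged_topic_skipped_with_warning(self):
        run, gold = self._setup()
        run.append(_entry("Z", 1, 0, 10, topic="99"))
        with pytest.warns(UserWarning):
            report = evaluate_run(run, gold, levels=("document",))
        assert set(report.per_topic["document"]) == {"1", "2"}

    def test_topic_order_irrelevant(self):
        run, gold = self._setup()
        a = evaluate_run(run, gold)
        b = evaluate_run(list(reversed(run)), list(reversed(gold)))
        assert a.map == b.map

    def test_all_aps_within_unit_interval(self):
        run, gold = self._setup()
        report = evaluate_run(run, gold)
        for level in report.per_topic.values():
            for ap in level.values():
                assert 0.0 <= ap <= 1.0


class TestCompareReports:
    def test_relative_improvement(self):
        run, gold = TestEvaluateRun()._setup()
        base = evaluate_run(run, gold, levels=("document",))
        improved = evaluate_run(run, gold, levels=("document",))
        object.__setattr__(base, "map", {"document": 0.20})
        object.__setattr__(improved, "map", {"document": 0.25})
        out = compare_reports(base, improved)
        assert out["document"] == pytest.approx(25.0)

    def test_identical_reports_zero(self):
        run, gold = TestEvaluateRun()._setup()
        rep = evaluate_run(run, gold)
        assert all(v == 0.0 for v in compare_reports(rep, rep).values())

    def test_zero_baseline_marked_not_applicable(self):
        run, gold = TestEvaluateRun()._setup()
        base = evaluate_run(run, gold, levels=("document",))
        object.__setattr__(base, "map", {"document": 0.0})
        other = evaluate_run(run, gold, levels=("document",))
        assert compare_reports(base, other)["document"] is None
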