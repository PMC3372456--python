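"""Association enumeration, observation matrix and communality ranking."""

import numpy as np
import pytest
from scipy.linalg import eigh as scipy_eigh
from scipy.stats import ortho_group

from termassoc.associations import (
    AssociationTerm,
    DegenerateModelError,
    association_present,
    build_observation_matrix,
    communalities,
    enumerate_associations,
    fit_factor_model,
    rank_associations,
    score_associations,
)
from termassoc.io import TermFileEntry, TopicRecord
from termassoc.query import extract_keywords


def oracle_communalities(values: np.ndarray, rule="kaiser") -> np.ndarray:
    """From-scratch eigendecomposition oracle, independent of the library path.

    Standardizes rows, forms the correlation matrix explicitly, uses scipy's
    symmetric eigensolver, retains factors per *rule*, and sums squared
    loadings. Zero-variance rows get communality 0.
    """
    X = np.asarray(values, dtype=float)
    p, N = X.shape
    sd = X.std(axis=1)
    keep = np.where(sd > 0)[0]
    Z = (X[keep] - X[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]
    corr = np.array([[float(np.mean(Z[i] * Z[j])) for j in range(len(keep))]
                     for i in range(len(keep))])
    evals, evecs = scipy_eigh(corr)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    evals = np.maximum(evals, 0.0)
    if rule == "kaiser":
        m = int((evals > 1.0).sum())
    elif rule == "mp":
        m = max(1, int((evals > (1 + np.sqrt(len(keep) / N)) ** 2).sum()))
    else:
        m = int(rule)
    h2 = np.zeros(p)
    for j in range(m):
        h2[keep] += evals[j] * evecs[:, j] ** 2
    return h2


class TestEnumeration:
    def test_n3_exhaustive(self):
        terms = [t.keyword_indices for t in enumerate_associations(3)]
        assert terms == [(0,), (1,), (2,), (0, 1), (0, 2), (1, 2), (0, 1, 2)]

    def test_n9_count_is_129(self):
        assert len(enumerate_associations(9)) == 129  # C(9,1)+C(9,2)+C(9,3)

    def test_n1_single_term(self):
        assert len(enumerate_associations(1)) == 1

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            enumerate_associations(0)

    def test_indices_must_ascend(self):
        with pytest.raises(ValueError):
            AssociationTerm((2, 1))
        with pytest.raises(ValueError):
            AssociationTerm((0, 1, 2, 3))


@pytest.fixture(scope="module")
def lupus_keywords():
    return extract_keywords(TopicRecord("200", "activity disease lupus serum"))


class TestPresence:

    def test_all_components_present(self, lupus_keywords):
        term = AssociationTerm((0, 1, 2))  # activ diseas lupus
        assert association_present(term, {"activ", "diseas", "lupus"}, lupus_keywords) == 1

    def test_missing_component(self, lupus_keywords):
        term = AssociationTerm((0, 3))  # activ serum
        assert association_present(term, {"activ", "diseas", "lupus"}, lupus_keywords) == 0

    def test_empty_stem_set(self, lupus_keywords):
        for term in enumerate_associations(4):
            assert association_present(term, frozenset(), lupus_keywords) == 0


class TestObservationMatrix:
    def test_two_passage_example(self):
        ks = extract_keywords(TopicRecord("1", "serum lupus"))
        entries = [
            TermFileEntry("1", 1, 2, frozenset({"serum", "lupus"})),
            TermFileEntry("1", 2, 2, frozenset({"serum"})),
        ]
        m = build_observation_matrix(entries, ks)
        assert [t.keyword_indices for t in m.terms] == [(0,), (1,), (0, 1)]
        np.testing.assert_array_equal(m.values, [[1, 1], [1, 0], [1, 0]])
        np.testing.assert_array_equal(m.counts(), [2, 1, 1])

    def test_all_empty_passages_zero_matrix(self):
        ks = extract_keywords(TopicRecord("1", "serum lupus"))
        entries = [TermFileEntry("1", r, 2, frozenset()) for r in (1, 2, 3)]
        assert build_observation_matrix(entries, ks).values.sum() == 0

    def test_unknown_stem_rejected(self):
        ks = extract_keywords(TopicRecord("1", "serum lupus"))
        with pytest.raises(ValueError):
            build_observation_matrix(
                [TermFileEntry("1", 1, 2, frozenset({"zebra"}))], ks
            )

    def test_unigram_row_sums_are_keyword_passage_counts(self):
        ks = extract_keywords(TopicRecord("1", "serum lupus activity"))
        rng = np.random.default_rng(3)
        entries = [
            TermFileEntry("1", r, 3, frozenset(
                s for s in ("serum", "lupus", "activ") if rng.random() < 0.4))
            for r in range(1, 31)
        ]
        m = build_observation_matrix(entries, ks)
        for i, kw in enumerate(ks.keywords):
            assert m.counts()[i] == sum(kw in e.found_stems for e in entries)


class TestFactorModel:
    def test_identical_rows_worked_example(self):
        # two identical binary rows + one uncorrelated: correlation matrix
        # [[1,1,0],[1,1,0],[0,0,1]], eigenvalues {2,1,0}; retained factor
        # explains the duplicated pair completely -> communalities (1,1,0)
        data = np.array([[1, 1, 0, 0], [1, 1, 0, 0], [1, 0, 1, 0]])
        for rule in ("kaiser", "mp"):
            model = fit_factor_model(data, rule)
            np.testing.assert_allclose(
                sorted(model.eigenvalues), [0, 1, 2], atol=1e-12)
            np.testing.assert_allclose(model.communality, [1, 1, 0], atol=1e-9)
            assert communalities(model, percent=True)[0] == pytest.approx(100.0)

    def test_zero_variance_row_gets_zero_communality(self):
        data = np.array([[1, 1, 1, 1], [1, 0, 1, 0], [0, 1, 1, 0]])
        model = fit_factor_model(data, "kaiser")
        assert model.communality[0] == 0.0

    def test_all_constant_rows_degenerate(self):
        with pytest.raises(DegenerateModelError):
            fit_factor_model(np.ones((3, 5)))

    def test_single_passage_rejected(self):
        with pytest.raises(ValueError):
            fit_factor_model(np.array([[1], [0]]))

    @pytest.mark.parametrize("rule", ["kaiser", "mp", 2])
    def test_matches_eigendecomposition_oracle_on_random_matrices(self, rule):
        rng = np.random.default_rng(42)
        for _ in range(100):
            data = (rng.random((10, 50)) < 0.4).astype(int)
            if (data.std(axis=1) == 0).all():
                continue
            model = fit_factor_model(data, rule)
            np.testing.assert_allclose(
                model.communality, oracle_communalities(data, rule), atol=1e-8
            )

    def test_communality_sum_equals_retained_eigenvalue_sum(self):
        rng = np.random.default_rng(5)
        data = (rng.random((12, 60)) < 0.3).astype(int)
        model = fit_factor_model(data, "kaiser")
        assert model.communality.sum() == pytest.approx(
            model.eigenvalues[: model.m].sum(), abs=1e-8
        )
        assert (model.communality <= 1 + 1e-8).all()

    def test_rotation_invariance_of_communalities(self):
        rng = np.random.default_rng(6)
        data = (rng.random((8, 40)) < 0.5).astype(int)
        model = fit_factor_model(data, "kaiser")
        if model.m < 2:
            pytest.skip("need >= 2 retained factors for a rotation")
        Q = ortho_group.rvs(model.m, random_state=1)
        rotated = model.loadings @ Q
        np.testing.assert_allclose(
            (rotated**2).sum(axis=1), model.communality, atol=1e-9
        )

    def test_variance_rule_and_fixed_m(self):
        rng = np.random.default_rng(7)
        data = (rng.random((6, 30)) < 0.5).astype(int)
        full = fit_factor_model(data, ("variance", 1.0))
        assert full.m >= fit_factor_model(data, 1).m == 1
        with pytest.raises(ValueError):
            fit_factor_model(data, ("variance", 1.5))
        with pytest.raises(ValueError):
            fit_factor_model(data, "unknown-rule")


class TestRanking:
    def _scores(self, matrix_entries, ks):
        m = build_observation_matrix(matrix_entries, ks)
        return m, score_associations(m, fit_factor_model(m, "kaiser"))

    def test_top_k_by_communality(self):
        ks = extract_keywords(TopicRecord("1", "serum lupus"))
        rng = np.random.default_rng(8)
        entries = []
        for r in range(1, 41):
            stems = set()
            if rng.random() < 0.5:
                stems = {"serum", "lupus"}  # correlated pair
            if rng.random() < 0.5:
                stems.add("serum")
            entries.append(TermFileEntry("1", r, 2, frozenset(stems)))
        matrix, scores = self._scores(entries, ks)
        top1 = rank_associations(scores, k=1)
        assert len(top1) == 1
        assert top1[0].communality == max(s.communality for s in scores)

    def test_k_larger_than_n_prime_gives_full_list(self):
        ks = extract_keywords(TopicRecord("1", "serum lupus"))
        entries = [
            TermFileEntry("1", 1, 2, frozenset({"serum"})),
            TermFileEntry("1", 2, 2, frozenset({"lupus"})),
            TermFileEntry("1", 3, 2, frozenset()),
        ]
        _, scores = self._scores(entries, ks)
        assert len(rank_associations(scores, k=99)) == 3

    def test_ties_broken_by_count_then_enumeration_order(self):
        ks = extract_keywords(TopicRecord("1", "serum lupus activity"))
        # constant matrix columns except one passage; most rows zero-variance
        entries = [
            TermFileEntry("1", 1, 3, frozenset({"serum", "lupus"})),
            TermFileEntry("1", 2, 3, frozenset({"serum"})),
            TermFileEntry("1", 3, 3, frozenset({"serum"})),
        ]
        matrix, scores = self._scores(entries, ks)
        ranked = rank_associations(scores, k=len(scores))
        # zero-communality group ordered by higher count first
        zeros = [s for s in ranked if s.communality == 0]
        counts = [s.count for s in zeros]
        assert counts == sorted(counts, reverse=True)
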