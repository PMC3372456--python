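"""Factor-analysis scoring of query term associations.

Given a query with keywords k1..kn and the N first-round retrieved
passages, every ascending-index subsequence of 1-3 keywords (unigram,
bigram, trigram) is a candidate *term association*. Each association is an
observed binary variable over passages: 1 in a passage iff every component
keyword occurs there (set containment; word order and proximity inside the
passage are ignored). Stacking all n' = C(n,1)+C(n,2)+C(n,3) associations
gives the n' x N observation matrix T.

The associations are assumed to be linear functions of a small number m of
unobservable common factors, T = L F + eps. Loadings are obtained by
principal-component extraction on the correlation matrix of T: with
eigenpairs (lambda_j, v_j), the loading of association i on factor j is
sqrt(lambda_j) * v_ij, and factors are retained by the Kaiser rule
(lambda > 1) by default. The *communality*

    h2_i = sum_j l_ij^2   over retained factors

is the fraction of association i's variance explained by the common
factors, and is the importance/reliance score used for ranking. Note the
intercept (location) term is not part of h2: including it would break the
h2 <= 1 bound that the percent scale of the reported scores implies.

Communalities are invariant under orthogonal rotation of the retained
loadings, so no rotation is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .io import TermFileEntry
from .query import KeywordSequence


@dataclass(frozen=True)
class AssociationTerm:
    """Ascending tuple of 0-based indices into the keyword sequence."""

    keyword_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        idx = self.keyword_indices
        if not 1 <= len(idx) <= 3:
            raise ValueError("associations have 1 to 3 keywords")
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("keyword indices must be strictly ascending")

    def stems(self, keywords: KeywordSequence) -> tuple[str, ...]:
        return tuple(keywords.keywords[i] for i in self.keyword_indices)

    def display(self, keywords: KeywordSequence) -> str:
        # reported with component stems in lexicographic order
        return " ".join(sorted(self.stems(keywords)))


def enumerate_associations(n: int) -> list[AssociationTerm]:
    """All unigrams, then bigrams, then trigrams, each block in lex index order."""
    if n < 1:
        raise ValueError("need at least one keyword")
    terms: list[AssociationTerm] = []
    for size in (1, 2, 3):
        if size > n:
            break
        terms.extend(AssociationTerm(c) for c in combinations(range(n), size))
    return terms


def association_present(
    term: AssociationTerm, found_stems: frozenset[str] | set[str], keywords: KeywordSequence
) -> int:
    return int(all(keywords.keywords[i] in found_stems for i in term.keyword_indices))


@dataclass(frozen=True)
class ObservationMatrix:
    """n' x N binary matrix of association presence over retrieved passages."""

    terms: tuple[AssociationTerm, ...]
    values: np.ndarray  # shape (n', N), entries 0/1
    keywords: KeywordSequence

    @property
    def n_passages(self) -> int:
        return self.values.shape[1]

    def counts(self) -> np.ndarray:
        """Per-association passage counts (row sums)."""
        return self.values.sum(axis=1)


def build_observation_matrix(
    entries: Sequence[TermFileEntry], keywords: KeywordSequence
) -> ObservationMatrix:
    """Column j is the 1-0 association vector of the rank-(j+1) passage."""
    known = set(keywords.keywords)
    for e in entries:
        unknown = e.found_stems - known
        if unknown:
            raise ValueError(
                f"term-file entry rank {e.passage_rank} has stems not in the "
                f"query: {sorted(unknown)}"
            )
    terms = enumerate_associations(keywords.n)
    ordered = sorted(entries, key=lambda e: e.passage_rank)
    values = np.zeros((len(terms), len(ordered)), dtype=np.int8)
    for j, e in enumerate(ordered):
        for i, t in enumerate(terms):
            values[i, j] = association_present(t, e.found_stems, keywords)
    return ObservationMatrix(tuple(terms), values, keywords)


class DegenerateModelError(ValueError):
    """Every observed row is constant; no correlation structure exists."""


@dataclass(frozen=True)
class FactorModel:
    loadings: np.ndarray        # (n', m) over retained factors
    eigenvalues: np.ndarray     # all eigenvalues of the correlation matrix, desc
    m: int                      # retained factor count
    communality: np.ndarray     # (n',) in [0, 1]


def fit_factor_model(
    matrix: ObservationMatrix | np.ndarray,
    factor_rule: str | int | tuple[str, float] = "mp",
) -> FactorModel:
    """Principal-component factor extraction on the row correlation matrix.

    ``factor_rule`` selects how many factors to retain:

    * ``"mp"`` (default) — retain eigenvalues above the Marchenko-Pastur
      null edge ``(1 + sqrt(p/N))**2`` for p observed variables on N
      passages, but always at least one. The classical Kaiser cut-off at 1
      under-states the null: with tens of associations and a few hundred
      passages, eigenvalues of pure sampling noise routinely exceed 1, and
      retaining them hands spuriously high communalities to rare
      associations. The MP edge is the appropriate eigenvalue null
      threshold (the deterministic analogue of Horn's parallel analysis).
    * ``"kaiser"`` — retain eigenvalues > 1.
    * an explicit integer m.
    * ``("variance", frac)`` — smallest m whose eigenvalues sum to at
      least ``frac`` of the total.

    Zero-variance rows are excluded from the correlation matrix and get
    all-zero loadings (communality 0).
    """
    values = matrix.values if isinstance(matrix, ObservationMatrix) else np.asarray(matrix)
    n_vars, n_obs = values.shape
    if n_obs < 2:
        raise ValueError("need at least 2 passages to fit a factor model")
    X = values.astype(float)
    sd = X.std(axis=1)
    active = sd > 0
    if not active.any():
        raise DegenerateModelError("all association rows are constant")
    Z = (X[active] - X[active].mean(axis=1, keepdims=True)) / sd[active][:, None]
    corr = (Z @ Z.T) / n_obs
    # guard against round-off outside [-1, 1]
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]

    k_active = int(active.sum())
    if factor_rule == "mp":
        edge = (1.0 + np.sqrt(k_active / n_obs)) ** 2
        m = max(1, int(np.sum(evals > edge)))
    elif factor_rule == "kaiser":
        m = int(np.sum(evals > 1.0))
    elif isinstance(factor_rule, int):
        if not 1 <= factor_rule <= k_active:
            raise ValueError("fixed factor count out of range")
        m = factor_rule
    elif isinstance(factor_rule, tuple) and factor_rule[0] == "variance":
        frac = float(factor_rule[1])
        if not 0 < frac <= 1:
            raise ValueError("variance fraction must be in (0, 1]")
        cum = np.cumsum(evals) / evals.sum()
        m = int(np.searchsorted(cum, frac) + 1)
    else:
        raise ValueError(f"unknown factor rule {factor_rule!r}")
    m = max(m, 0)

    loadings_active = evecs[:, :m] * np.sqrt(evals[:m])
    loadings = np.zeros((n_vars, m))
    loadings[active] = loadings_active
    h2 = (loadings**2).sum(axis=1)
    return FactorModel(loadings=loadings, eigenvalues=evals, m=m, communality=h2)


def communalities(model: FactorModel, percent: bool = False) -> np.ndarray:
    h2 = model.communality
    return 100.0 * h2 if percent else h2


@dataclass(frozen=True)
class AssociationScore:
    term: AssociationTerm
    count: int
    communality: float  # h2 on the [0, 1] scale

    @property
    def communality_pct(self) -> float:
        return 100.0 * self.communality


def score_associations(
    matrix: ObservationMatrix, model: FactorModel
) -> list[AssociationScore]:
    counts = matrix.counts()
    return [
        AssociationScore(t, int(counts[i]), float(model.communality[i]))
        for i, t in enumerate(matrix.terms)
    ]


def rank_associations(scores: Sequence[AssociationScore], k: int = 10) -> list[AssociationScore]:
    """Top-k by communality; ties broken by higher count, then enumeration order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    indexed = list(enumerate(scores))
    indexed.sort(key=lambda pair: (-pair[1].communality, -pair[1].count, pair[0]))
    return [s for _, s in indexed[:k]]
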