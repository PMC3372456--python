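# Methods

This note records the model, the numerical choices, and the reasoning
behind the design decisions that were genuinely open, in enough detail to
re-derive every default in the code.

## Text processing

Tokenization is shared by documents and queries: lowercase, split on
non-alphanumeric runs, Porter-stem each token. The stemmer implements the
classical five-step suffix-stripping algorithm with longest-match rule
selection within a step, plus one deliberate deviation: the bare `S →`
rule of step 1a is guarded against words ending in `-us` or `-as`.
Textbook Porter maps *lupus* → *lupu* and *pancreas* → *pancrea*, damaging
exactly the Latin/Greek singulars that matter in biomedical text; the
guard keeps them intact. It also makes the pipeline stable on its own
output for query stems such as *diseas* (textbook Porter would strip the
final *s* again on re-application). The cost is that a few `-as` plurals
(*areas*, *ideas*) no longer conflate with their singulars — an acceptable
trade in this domain. The stopword list is a compact classical English IR
list (~320 words), configurable per call.

Keyword sequences keep first-appearance order and deduplicate on stems;
bracketed entity markers like `[PROTEINS]` contribute their inner token
because bracket characters are simply token separators.

## Passages and indexing

A passage is a contiguous character span of a document with the stem
multiset derived from exactly that span; offsets are 0-based character
indices into tag-stripped text and spans are half-open. Three
granularities: `paragraph` (one passage per `<p>`-delimited span, with a
whole-document fallback when no markup exists), `sentence` (disjoint
consecutive groups of up to 3 sentences within a paragraph — disjoint
rather than sliding so that character-level evaluation never counts the
same text twice), and `word` (fixed token windows, default 35 tokens every
17, final short window kept unless fully contained in the previous one).
The word windows are a fixed-size stand-in for dynamic-window extraction
and are documented as an approximation. Sentence boundaries are `.`, `!`
or `?` followed by whitespace or end of text.

## BM25 first round

The per-term weight is the standard Robertson–Spärck Jones BM25 form with
K = k1·((1−b) + b·dl/avdl), a query-term factor (k3+1)·qtf/(k3+qtf), and a
once-per-passage length correction k2·nq·(avdl−dl)/(avdl+dl). Defaults
k1 = 1.2, b = 0.75, k2 = 0, k3 = 8; natural logarithm (the base is a
documented constant — any base rescales all weights equally and leaves
every ranking unchanged). No relevance feedback is used in first-round
runs (R = r = 0), so the log factor reduces to ln((N−n+0.5)/(n+0.5)).
b > 1 is permitted (the evaluation grid uses b = 2.0 and 1.3); if a
short passage then drives K + tf ≤ 0 the weight is undefined and an error
is raised rather than silently clamped. Ties in weight are broken by
(doc_id, offset) so runs are fully deterministic. Retrieval returns the
top 1000 matching passages by default; passages containing no query
keyword are never retrieved.

## The factor-analysis association model

Associations are ascending-index subsequences of 1–3 query keywords;
presence in a passage is set containment of all component stems (order and
proximity inside the passage are deliberately ignored — that distinction
is exactly what separates this model from sequence mining). The n' × N
binary observation matrix is standardized per row; its correlation matrix
is eigendecomposed; loadings are √λj·vij; the communality h² of each
association is its sum of squared loadings over retained factors.
Zero-variance rows (associations present in no or in every retrieved
passage) carry no information and get communality 0; they rank last.
Communality is invariant under orthogonal rotation of the retained
loadings, so no rotation is applied. The intercept term is not part of
h² — including a location term would break the h² ≤ 1 bound that the
percent reporting scale implies.

**Factor retention.** The default retains eigenvalues above the
Marchenko–Pastur null edge (1 + √(n'/N))², with a floor of one factor;
Kaiser (λ > 1), fixed m, and cumulative-variance rules are selectable.
The Kaiser rule is the textbook default but is measurably wrong at this
design size: with n' ≈ 14–41 association rows and N ≈ 500 passages, the
largest eigenvalue of a pure-noise correlation matrix concentrates near
the MP edge ≈ 1.5–1.65, so "λ > 1" retains several factors that are
sampling artifacts. Because rare associations (a handful of occurrences in
500 passages) can be nearly collinear with each other by chance, those
noise factors hand them communalities close to 1 and swamp any real
structure. Retaining only above-edge factors removes that pathology while
keeping every factor a null model cannot produce; it is the deterministic
analogue of Horn's parallel analysis.

Ranking is by descending communality, ties broken by higher passage count,
then enumeration order (unigrams, bigrams, trigrams, each block in
lexicographic index order). The default cutoff is k = 10, which saturates:
associations beyond the first few contained ones never change the re-rank.

## Recursive re-ranking

The ranked associations T'1..T'k induce a binary partition tree over the
run: at each level the passages containing the association precede those
that do not, and leaves are ordered by descending original weight (stable,
so equal weights keep first-round order). Weights are never recomputed.
The whole procedure equals a stable sort by the key
(−contains(T'1), …, −contains(T'k), −weight); the test suite checks the
recursive implementation against that sort oracle exactly, on 200 random
instances. Ranks are reassigned 1..M and the run label gets a `-ta`
suffix.

## GSP comparator

Keywords are singleton items; each document's retrieved passages, ordered
by offset, form its data sequence. A candidate (an ascending keyword
subsequence) is contained if its keywords can be matched at non-decreasing
passage positions — one passage holding everything and keywords scattered
over successive passages both count. Mining is level-wise with Apriori
pruning, capped at the query length. The minimum support is data-driven:
the empirical distribution of all candidate support counts is taken as is
(no parametric fit) and its 2.5th percentile — the lower bound of a
central 95% interval, linear interpolation between order statistics,
floored at 1 — is the threshold. GSP re-ranking reuses the recursive
re-ranker with the top-k frequent sequences under *document-level*
containment, so both re-rankers differ only in how associations are chosen
and matched. The document-level semantics deliberately preserve the known
failure mode: a document whose keywords never share a passage is still
boosted, which is why GSP trails the factor model at the passage levels.

## Evaluation measures

*Document AP*: run entries map to documents, repeats after the first are
ignored, precision is recorded at each first retrieval of a relevant
document, and the sum is divided by the number of relevant documents.

*Passage AP* (character-based): walking the run in rank order, at every
rank whose passage overlaps ≥ 1 gold character, cumulative overlapping
characters over cumulative nominated characters is recorded; the sum of
recorded precisions is divided by the topic's gold span count (unretrieved
gold spans contribute 0). A gold character is credited once in the
numerator even if nominated repeatedly — otherwise AP could exceed 1 — but
the denominator counts every nomination. The divisor choice (gold spans,
not gold characters) is documented rather than claimed byte-compatible
with any official scorer, since official definitions drifted across track
years.

*Passage2 AP*: the run expands to a character stream in published (rank,
then in-passage) order; characters already emitted for the same document
are dropped (first emission wins, which makes the measure stable under
arbitrary passage splitting); each character is relevant iff inside a gold
span; standard AP over the stream with total relevant = the topic's
distinct gold character count.

The aspect-level measure is named in the track definitions but no aspect
results are modelled here; it is out of scope.

## Synthetic collections

Each paragraph draws a latent factor f ~ N(0,1); keyword i appears with
probability logistic(αi + λi·f). Keywords with λ > 0 therefore co-occur
beyond independence — the correlation structure the factor model assumes —
while λ = 0 keywords are independent given the text. Paragraphs with f
above the (1 − relevant_fraction) normal quantile are relevant; their
exact character spans are the gold standard. Keyword surface forms are
Porter-stable (stem = surface) to decouple generator tests from the
stemmer; filler words are drawn uniformly from a synthetic vocabulary that
is checked for collisions with the keywords. Everything is a deterministic
function of (spec, seed).

Defaults: 160 documents × 5 paragraphs × 3 sentences (800 passages), 4
query keywords at marginal presence ≈ 0.20 (α = −1.4), relevant fraction
0.2. The planted variant raises the planted pair to α = −0.8 with λ = 2,
giving marginals ≈ 0.4 and a planted joint presence far above the product
of marginals. The asymmetry is intentional and mirrors real per-topic term
files, where topical keywords appear in a few hundred of 1000 retrieved
passages and peripheral ones in well under a hundred. It is also what
makes recovery well-posed: every bigram is structurally correlated with
its own component unigrams (corr ≈ √p for marginal p), so if all keywords
are common, independent bigrams' communalities rival a λ = 2 planted
bigram's *in population* and no estimator could single the planted one
out; if background keywords are too rare, their near-empty rows become
exactly collinear by chance and produce degenerate high-communality pairs.
Between those regimes the planted bigram is the population-top
communality, and the 50-replicate study recovers it in the top 3 in
≈ 98–100% of seeds with document MAP never hurt by re-ranking.

What the generator does *not* emulate: real biomedical vocabulary and
morphology, document-length and paragraph-length variation, topic drift
within documents, multi-factor dependence (a single latent factor is
planted; multi-factor planting would be a configuration extension), and
judge disagreement in the gold standard. Passing the recovery study
therefore shows the estimator chain is sound under its own modelling
assumptions, not that those assumptions hold on any particular real
collection.

## Numerical and degenerate-input choices

- Correlation entries are clipped to [−1, 1] and eigenvalues to ≥ 0 before
  use; communality agreement with an independent eigendecomposition oracle
  is asserted to 1e-8.
- All-constant observation matrices raise a degenerate-model error; a
  single retrieved passage (N < 2) is an error.
- Empty queries (all stopwords) raise rather than returning an empty
  sequence.
- An empty first-round run (no passage contains any keyword) is a valid
  empty result, not an error.
- Weight ties and equal communalities have total deterministic orderings
  (documented tie-breaks), so every artefact is reproducible byte-for-byte
  from (inputs, config, seed).

## Problem sizes used in validation

The replicated studies use 800-passage collections with 500 passages
retrieved per run, 50 seeded replicates per study; oracle comparisons use
100 random 10×50 matrices, 200 random re-rank instances, and 100 random
GSP databases. These sizes give the studies stable rates (repeat runs with
different seed bases vary by at most a few percent) while the whole
validation suite completes in seconds.
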