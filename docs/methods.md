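# Methods

This note documents the models and procedures implemented in `biomedqa`,
the parameters that matter, what the synthetic fixtures do and do not
emulate, and the design choices made where the design was genuinely open.

## Pipeline overview

A question is processed in three phases. *Question processing*: annotation
(tokens, sentences, POS, lemmas, base NPs), wh-word and question-type
detection, focus detection, and generation of weighted candidate search
terms with morphological, nominalization, and acronym expansions.
*Document processing*: assembly of a conjunction-of-OR-groups boolean
query, optional protection of classifier-selected keywords, and greedy
iterative relaxation against a positional inverted index until documents
are returned. *Answer processing*: sentence segmentation (title as
sentence 0), similarity scoring, focus-entity-type filtering for factoid
questions, definition-pattern promotion for definition questions, optional
supervised reranking, and exact-answer phrase extraction.

## Vocabulary, phrases, IDF

Multi-word phrases (2–4 tokens) are mined with Dunning's log-likelihood
ratio collocation test; an n-gram qualifies when its weakest adjacent-join
score reaches the threshold (default 30, roughly the χ²₁ tail far beyond
conventional significance — deliberately conservative for sparse counts)
and it occurs at least `min_count` times (default 5). Longer n-grams only
grow from accepted shorter spans, keeping the candidate lattice sparse.
The test statistic itself was validated against an independent G-test
implementation.

Document frequencies are counted at the document level over the
title+abstract token stream (phrases as contiguous token runs), and
`idf = ln(N_docs / df)` — the conventional formula; no additional global
normalization is applied because the ranking score normalizes by the
question's weight sum. Terms absent from the vocabulary receive the
maximum observed IDF when they come from the question (rare biomedical
surface forms are the terms most worth keeping) but contribute zero when
they are unmatched tokens inside an out-of-vocabulary disjunct of the
construct-weight formula (there is no evidence they carry signal).

## Ranking score

The score is the IDF-weighted mean, over unique question terms, of each
term's maximum cosine similarity to any unique answer term. This is
exactly the optimum of the transport problem with the demand constraint
removed — each question term ships its whole mass to its most similar
answer term — which the test suite verifies against a linear-programming
oracle to 1e-9 on a thousand random instances. Properties that follow and
are asserted: identity (a fully embedded question scores 1 against
itself), invariance to duplicated answer terms, and invariance to
orthogonal additions.

Numerical/degenerate choices: cosine of a zero vector is defined as 0
with a logged warning (degenerate embeddings must not abort ranking); an
empty answer sentence scores 0; a question term with no embedding scores
1 on exact surface match in the answer and 0 otherwise; stop-words (a
packaged ~100-word list) are removed from both term sets before scoring
because they otherwise dominate max-cosine matches; vocabulary phrases
replace their constituent words via greedy longest-match. Sorting is
stable with ties preserving document order, then sentence order.

## Query construction and relaxation

One OR-group per NP (plus number variants and acronym expansions), one per
non-copula verb (plus conjugations and nominalizations), one per
vocabulary-validated subphrase and per individual NP word. Disjuncts are
sorted descending by weight, ties lexicographic; groups keep their
left-to-right question order as the deterministic tie-break.

Relaxation drops one disjunct per iteration. Priority: (1) verb groups,
always first and down to empty — verbs are the least reliable retrieval
cues; (2) unprotected multi-disjunct groups by ascending maximum disjunct
weight, lowest-weight disjunct first; (3) unprotected singletons (their
removal is what widens the result set, since dropping a disjunct from a
surviving OR-group only narrows it); (4) protected (entity/focus) groups,
multi-disjunct before singleton, as the last resort. The first state with
at least one hit is returned; when that state exceeds the hit cap
(default 1000) it is accepted and truncated — it is still the most
specific non-empty query available. Termination is bounded by the total
disjunct count; exhaustion returns an explicit flag rather than an error.
A standalone policy simulator in the test suite replays the drop order
independently.

The search backend is a two-method contract; the reference implementation
is an in-memory inverted index with token positions (phrase contiguity is
checked positionally), scoring matches by the summed weight of the best
matched disjunct per group with doc-id tie-breaks. An adapter to an
external engine (mapping OR-groups to should-clauses inside a bool/must
query) can implement the same contract; none is bundled.

## Focus detection and entity typing

Precedence when several rules could fire: the NP immediately after the
wh-word, else the first NP after a copula/auxiliary that directly follows
the wh-word, with a single application of the of/in prepositional rule
(the post-preposition NP becomes the focus, the pre-preposition NP its
modifier). The focus head is mapped to one of the nine entity types
(gene, protein, enzyme, disease, drug, molecular entity, organism,
anatomical entity, cellular component) through a configurable trigger
table, falling back to gazetteer lookup of the whole phrase. Entity
recognition is gazetteer lookup with greedy longest-match left-to-right;
matching is on surfaces, not lemmas.

The built-in annotator is a deterministic fallback: regex tokenizer
(hyphenated identifiers like "miR-21" stay single tokens; slash compounds
split), closed-class lexicon plus suffix heuristics for POS, rule-based
sentence splitting with an abbreviation guard, and base (non-recursive)
NP chunks. It trades accuracy for exact reproducibility; an industrial
parser can be injected through the annotator contract, and the pipeline
consumes only the products both can provide (tokens, sentences, POS,
lemmas, NP chunks). Acronym definitions are aligned with the standard
right-to-left character-matching algorithm for parenthetical
abbreviation–definition pairs.

## Keyword selector

Questions are encoded to exactly 40 positions (zero-padded/truncated;
40 output neurons, one per token) of embedding vectors; out-of-vocabulary
tokens map to zero vectors. Architectures: `dense` (flattened input →
position sigmoids), `lstm` (per-timestep readout of a unidirectional
LSTM, hidden size 24), `conv1d` (32 same-padded width-3 ReLU filters),
and multi-input variants (`dense_dense`, `lstm_dense`, `lstm_lstm`) that
pass one-hot POS tags through an 8-unit ReLU layer before concatenation.
Defaults: dropout 0.2, threshold 0.5, 8-fold cross-validation, Adam with
learning rate 0.02, 60 epochs, batch 32 — sized for the few-hundred-
question training sets this component targets. All layers are seeded
numpy implementations; training is exactly reproducible, and per-fold
precision/recall/F1 exclude padding positions.

The synthetic training set plants the rule *keyword ⇔ content-lexicon
membership XOR previous-token-is-blocker* over embeddings that carry the
content and blocker indicators as latent coordinates. The XOR override is
deliberate: a plain lexical rule is linearly separable from the flattened
input, which would let the dense baseline tie the recurrent encoder; the
contextual exception preserves the qualitative ordering (recurrent >
positionless) that motivates the LSTM while keeping the rule exactly
recoverable (observed fold F1 1.0 vs ≈0.77 for dense). What this shows is
that the architectures train correctly and context helps when context
matters — not that these F1 values transfer to real question annotations,
which are noisier and lexically far richer. A loader for externally
deposited keyword annotations (JSONL question/label records, whitespace
tokenization authoritative) supports training on real data offline.

Selected keywords *force-include* their constructs: those groups are
flagged protected so relaxation exhausts unselected groups first; among
protected groups the base drop order applies.

## Reranker

Sentence-pair classification: per answerable question, the annotated
first-correct candidate is the one positive and the remaining pool
members (pool 100, sequence cap 64 by default) are negatives — noisy by
construction, since correct answers below the first occurrence stay
negative. The default backend is a bag-of-embeddings logistic regression
(mean-pooled question and sentence vectors, their absolute difference and
elementwise product) with balanced class weights so the one-vs-pool
imbalance does not crush the probability scale. The backend is a
two-method contract (`fit(pairs)`, `score(question, sentence)`); a
transformer fine-tuning adapter can be substituted without touching the
pipeline, and reranking itself is backend-agnostic: candidates are sorted
by predicted probability, stable with the similarity order as tie-break.

## Exact answers

From the top 10 ranked sentences. Entity path (focus type recognized):
unique entities of that type, first-occurrence order, unscored. NP path:
all NPs with leading determiners/demonstratives/predeterminers/
comparatives/superlatives/cardinals/adverbs stripped, subphrases included
for 3–5-token NPs; bare generic type words removed (configurable
stoplist seeded with the nine type names); candidates with cosine ≥ 0.8
to any question noun/NP removed (a question rarely contains its own
answer); survivors scored `cos(candidate, focus) × TF × IDF` with term
frequencies over the ten sentences, ties by sentence rank then surface.
Out-of-vocabulary phrases back off to the mean of their embedded tokens,
then to score 0; subphrases inherit their parent NP's sentence rank.

## Evaluation

MRR with unanswered questions contributing 0, and Precision@1; P@1 ≤ MRR
always (asserted). Automatic gold alignment — first candidate within a
200-sentence window containing any gold string at token boundaries, any
single list item sufficing for list questions — is explicitly heuristic
and flagged as such in reports; it exists for regression testing, not as
a replacement for human judgment.

## Synthetic fixtures: what they do and do not show

The end-to-end fixture (default 50 documents, 5 planted QA pairs,
32-dimensional embeddings, 8 gazetteer entries per type) constructs
embeddings from orthogonal topic directions plus small seeded noise and
writes answer sentences containing the question's content terms exactly,
so each planted answer is *uniquely optimal* under the ranking score and
recovery at rank 1 is a deterministic property of the construction.
Passing it demonstrates that the stages compose correctly — retrieval
finds the planted document, ranking puts the planted sentence first, the
focus filter keeps it, extraction returns the planted entity. It does not
demonstrate robustness to the ambiguity, synonymy, or length variation of
real abstracts, nor retrieval quality at corpus scale; those depend on
real embeddings and a real index, which the loaders and backend contracts
accommodate but the test suite does not require.

## Known limitations

Lookup-based entity recognition misses surface variants absent from the
gazetteers; the fallback annotator's POS and NP quality bounds question
analysis on convoluted phrasings; coordination handling is limited to
comma/and/or lists within a sentence; list-question answer aggregation
and multi-sentence (passage) answers are out of scope; the bundled
reranker backend cannot capture word-order or long-range semantics — it
is the contract's reference implementation, not its ceiling.
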