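# Methods

This note records the model, the defaults that matter, the numerical
choices, and what the synthetic fixtures do and do not establish.

## Pipeline

Raw text is cleaned to letters, digits, whitespace and common punctuation
(`.,;:!?()[]-'"/%+`), split into sentences at `.!?` boundaries guarded by
an abbreviation list ("Fig.", "et al.", "e.g."), and analyzed into three
aligned streams per sentence: raw tokens with character offsets, lowercase
lemmas, and Penn-style POS tags. Stopword/punctuation removal only selects
`content_indices`; the raw stream is never altered, because entity
matching, context windows and dependency parsing all legitimately consume
function words ("to", "with").

The tokenizer, lemmatizer and POS tagger are deterministic rule systems
shipped with the package (the stopword inventory is a versioned file under
`lpitext/data/`), so every downstream feature is bit-reproducible. The
lemmatizer is an inflection stripper (irregular table plus -s/-es/-ies,
-ed, -ing rules with Porter-style stem repair); it is tuned to normalize
the interaction vocabulary exactly (binds/binding/bound → bind,
associations → association) and is not a full morphological analyzer. The
tagger is a closed-class lexicon plus suffix heuristics; symbol-like
biomedical names (BC1, Eif4a1, NF-kB) tag as proper nouns.

## Named entity recognition

Dictionary matching is greedy longest-match, left-to-right, over raw
tokens, under a normalization policy that is case-insensitive and
hyphen/space-insensitive ("NF kB" ≡ "NF-kB" ≡ "nfkb"). Lexicons are
deduplicated per entity type under the same policy; the two types are
independent namespaces. Longest-match and the advance-past-match scan are
design choices (no tie-breaking convention is canonical for dictionary
NER); they guarantee that no reported mention of a type is a strict
sub-span of another. A statistical tagger can be plugged in through a
one-method protocol; its mentions are reported separately and never merged
with dictionary mentions. No tagger is trained here.

The classification unit is the candidate pair: every (lncRNA mention ×
protein mention) combination within one sentence, minus overlapping spans.

## Features

| block     | size    | content |
|-----------|---------|---------|
| semantic  | d (200) | mean embedding of content lemmas |
| syntactic | d (200) | mean embedding of tokens in parse DFS order |
| distance  | 12      | cosine distances of ≤3 context words per side per entity |
| pos       | 22      | one-hot head-token POS per entity, 11 categories |

Pooling. Word sequences of variable length must become a fixed classifier
input; the reduction is not dictated by the feature definitions. The
default is the arithmetic mean, the simplest order-free reduction. Under
mean pooling a full-tree DFS sequence is a permutation of the sentence, so
the syntactic block equals the semantic block computed over all raw tokens
(they still differ because the semantic block drops stopwords). An
order-preserving alternative, `pooling="pad_concat"` (concatenate the
first `max_len` vectors, zero-padded), is provided for experiments where
the traversal order itself should carry signal.

Syntactic scope. The DFS runs over the full dependency tree by default —
the worked traversal of "Bc1 RNA associates with Pura" visits all five
tokens. A shortest-dependency-path-only mode (`sdp_only`) restricts the
sequence to the path between the two entity heads; which scope is
preferable is an open empirical question and both are exposed.

Parsing is a plug-in contract (tokens, POS tags) → (parent indices, root).
The shipped `HeuristicParser` is deterministic: first verb-tagged token as
root, left tokens chained rightward, right tokens chained leftward. It is
a reproducible stand-in adequate for synthetic text, not a trained parser;
any parser failure degrades to a linear chain (DFS = sentence order) with
a logged warning.

Distance block conventions: slots are [lnc left ×3, lnc right ×3, prot
left ×3, prot right ×3]; absent context positions hold the sentinel 0. A
zero (out-of-vocabulary) vector makes the cosine undefined, and is also
mapped to sentinel 0 — OOV context words are deliberately
indistinguishable from absent ones. Multi-token entity embeddings are the
mean of their token vectors; the entity head token is the last token of
the span (head-final English noun phrases).

POS categories, in fixed order: proper-noun, noun-singular, noun-plural,
verb-base, verb-3sg, verb-past/participle, adjective, adverb, preposition,
determiner, closed-class. Noun-singular sits at index 1, so NN encodes as
[01000000000]. Tags outside the inventory (FW, punctuation) encode as all
zeros and are logged.

Embedding fallback chain: providers are consulted in priority order (a
retrained domain table before a general one); the first hit wins, so
adding a later provider never changes vectors for covered words. The
bundled trainer implements the skip-gram objective with negative sampling
(5 negatives), dynamic window (default 5), frequent-word subsampling
(t = 0.001) and a linearly decaying learning rate, in pure numpy, seeded
and deterministic. It is meant for small domain corpora; large-scale
pretrained tables are read from word2vec text format.

## Corpus labeling rules

Positive: the pair's canonical names are in the reference interaction set
(normalization as in NER). Reference match takes precedence over
everything — negatives must not be in the reference set — so a reference
pair in a negated sentence stays positive.

Negative condition 1: no interaction keyword anywhere in the sentence
(whole-sentence scope); negation words are irrelevant here. Condition 2:
at least one keyword and at least one negation word. A non-reference pair
with a keyword and no negation is ambiguous and dropped, mirroring a
manually filtered corpus rather than auto-labeling. The two conditions
are mutually exclusive by construction.

Keyword matching is by lemma: the five bases plus an explicitly enumerated
derivational noun map (association, correlation, binding, interaction,
enrichment) — deliberately closed, not open-ended morphology. The negation
inventory (no, not, without, neither, nor, lack, absence, fail, unable,
never, cannot) is this package's own default, fully configurable;
reproduction of any given corpus depends on it.

## Classifier and evaluation

Logistic regression with L2 regularization; `C` = 1.0 and `max_iter` =
1000 by default, with `grid_search_C` selecting C ∈ {0.01, 0.1, 1, 10,
100} by mean CV F1 when tuning is wanted. Continuous blocks (semantic,
syntactic, distance) are standardized to zero mean / unit variance with
statistics fitted on training folds only — embedding magnitudes would
otherwise dominate the mixed-scale input; the binary POS block is left
untouched. Cross-validation is stratified (fold class ratios within one
example of the global ratio), shuffled under a fixed seed; reported cell
means are the arithmetic means of per-fold metrics, with per-fold
confusion counts retained so the identities accuracy = (TP+TN)/N,
P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R) can be re-checked on every
cell (degenerate ratios report 0 and are flagged). Note that averaging F1
per fold is not the same as the harmonic mean of averaged P and R; the
per-fold convention is used throughout. Precision-recall curves come from
out-of-fold scores; the recall-0 endpoint takes precision 1 by convention.

Comparators (SVM, random forest, lightgbm, xgboost) are reached through
`make_estimator`; they are external library estimators, never
reimplemented, and a missing optional backend skips its grid cells with a
notice. Model serialization is versioned JSON (weights, intercept,
standardization parameters, feature signature, seed) and covers the
built-in logistic-regression kind; prediction refuses a feature vector
whose configuration signature differs from training.

## Synthetic fixtures

`generate_corpus` plants truth: positive sentences embed a reference pair
plus an interaction keyword; condition-1 negatives co-mention a
non-reference pair with no keyword; condition-2 negatives add a keyword
and a negation. Reference and negative pairs come from disjoint slices of
the name-pair space, so rule recovery is exact by construction — the
recovery tests check the implementation, not the difficulty of the task.
Templates cover sentence-initial and sentence-final entities (degenerate
context windows). Entity pools mix well-known names (BC1, Pura, Eif4a1,
H19, Igf2, MALAT1, EZH2) with synthetic ones so the worked examples run
verbatim.

Class signal is a mean shift: each class draws filler words from its own
pool and pool vectors are shifted ±signal/2 along one axis, giving a
class-conditional mean separation of `signal`. At signal 0 both classes
share one pool, making them exchangeable; `matched_templates` +
keyword-bearing-negatives-only removes the residual lexical asymmetry for
null-calibration experiments. Word vectors are hash-seeded unit-norm
gaussians — identical across runs, platforms and vocabulary orderings.

Test-scale defaults are dim 16 and corpora of a few hundred sentences;
dimension-dependent assertions are parameterized, and the reference
dimension 200 is exercised through the dimensional contracts. The
acceptance script uses n = 500 (separable check) and n = 1000 × 20 seeds
(permutation null), sizes at which the binomial noise on a mean CV
accuracy is well under a percentage point.

What passing does not show: synthetic sentences are short templated
English with clean entity boundaries and a perfectly matched lexicon. Real
abstracts bring misspelled and novel entity names, nested and ambiguous
mentions, long-range syntax that the heuristic parser cannot capture, and
interaction assertions phrased outside the five-keyword vocabulary.
Metrics on the synthetic corpora say the machinery is correct, not that
comparable accuracy transfers to PubMed text; benchmarking on a real
curated corpus with large pretrained embeddings is the intended follow-up
and runs through the same `evaluate` command.

## Known limitations

- Dictionary NER cannot find names absent from the lexicons; the tagger
  interface exists precisely to complement it, but no tagger is bundled.
- The rule engine treats negation lexically; scope is not analyzed
  ("not only ... but also" would be misread).
- The heuristic parser produces plausible but linguistically naive trees;
  plug in a trained parser for real text.
- Mean pooling discards word order; the syntactic block only adds
  information under `pad_concat` pooling or `sdp_only` scope.
- Remote document retrieval (PMID/PMCID) is out of scope by design; the
  `source_kind` field exists so such documents can be represented when
  fetched externally.
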