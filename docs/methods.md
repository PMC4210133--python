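# Methods

## Problem and model

`nanoct` addresses binary document categorization of clinical-trial
registry summaries: given the free text of a registered study, decide
whether the tested intervention is nanotechnology-based (*nano*) or
conventional (*non-nano*). Documents are represented as sparse
bag-of-words vectors over Porter-stemmed unigrams or bigrams, weighted by
one of four schemes, and classified by one of seven supervised families.
Evaluation uses stratified 10-fold cross-validation, leave-one-out (LOO)
and self-consistency testing with a chance-corrected metric suite.

## Record parsing

A study record is an XML document carrying an NCT accession
(`NCT` + 8 digits). The registry schema does not define a canonical
"summary text", so the package concatenates a configurable list of
free-text fields — default `brief_title`, `official_title`,
`brief_summary`, `detailed_description`, `condition`,
`intervention_type`, `intervention_name`, `keyword` — joined by single
newlines in document order. The newline is load-bearing downstream:
bigrams never cross it, so no artificial token pair spans two unrelated
fields. Whitespace inside a field is normalized; absent fields are
skipped. Record ordering in an assembled corpus is fixed by sorting on
NCT id so fold assignment is reproducible run to run.

## Dictionary retrieval

Candidate identification matches concept/synonym lists (e.g. exported
from a biomedical metathesaurus, `concept_id<TAB>term` rows) against the
raw case-folded surface token stream — deliberately *before* digit
masking, stop-word removal and stemming, because dictionary entries are
surface forms. Hyphens and all other punctuation separate tokens, making
matching invariant to surrounding punctuation. Multiword terms are
contiguous token phrases; `prefix` mode lets the final term token match
any token that begins with it, a capability registry search engines
typically lack and the reason simple keyword search under-retrieves
nano trials. Records reaching a threshold of distinct matched concepts
are proposed for human review; the package does not attempt to replicate
live search hit counts, which drift with the registry.

## Preprocessing

The normalization pipeline order is fixed and tested:

1. tokenize on any character that is not alphanumeric or underscore;
2. replace every digit with `#`;
3. lowercase;
4. remove stop words (a frozen English function-word list ships as
   package data so output cannot drift with third-party library
   versions; any list can be supplied);
5. drop tokens shorter than 3 characters;
6. Porter-stem the survivors.

Two consequences are deliberate. Masking precedes the length filter, so
`100 → ###` (length 3) survives while `50 → ##` does not: masked numbers
are treated as a generic "number was here" feature. Stemming runs last,
after the length filter, so a stem may end up shorter than three
characters (`ties → ti`); the filter applies to pre-stem tokens.

The stemmer is an in-package implementation of the original
suffix-stripping algorithm (steps 1a–5b, measure-based conditions,
longest-matching-suffix rule selection, words of length ≤ 2 untouched),
verified against the algorithm's canonical worked examples. It applies
no later extensions.

## Weighting

For feature t and document d over N training documents with document
frequency df(t):

| scheme      | weight                                |
|-------------|---------------------------------------|
| binary      | 1[t ∈ d]                              |
| frequency   | tf(t, d)                              |
| idf         | ln(N / df(t)) · 1[t ∈ d]              |
| tfidf       | tf(t, d) · ln(N / df(t))              |

The idf is the unsmoothed natural log: a term present in every training
document gets weight exactly 0 and disappears from the idf/tfidf
representations, which is the stated purpose of the transformation. The
"IDF representation" keeps presence only (tf is ignored), making it
distinct from both the binary and TF-IDF schemes; this reading is a
documented design choice. Optional normalization scales each nonzero row
to unit Euclidean norm. Vocabulary order is lexicographic; ties need no
further rule.

Held-out documents are vectorized with the *training* vocabulary, N and
df; unseen features are dropped. Inside every cross-validation split the
vocabulary and df are recomputed from the training documents alone. The
harness implements this with a column-restriction over a precomputed
global count matrix (features with training df = 0 are removed entirely),
which is mathematically identical to rebuilding the vocabulary per split
— including the smoothing denominators of the naive Bayes — and is tested
for the no-leakage property directly.

## Classifiers

Seven families share one contract: `train(matrix, labels, spec)` is
deterministic given the seed; `score` returns a positive-class score
(probability in [0, 1] for the logistic families, naive Bayes and the
tree; signed margin for the SVMs); `predict` thresholds at 0.5 / 0 with
ties going to the positive class. The convex optimization is delegated to
scikit-learn solvers; the module owns the hyperparameter surface and the
orientation of scores toward the *nano* class.

Defaults (all exposed on `ClassifierSpec`): penalty weight `lam = 1.0`
for the logistic families (solver cost C = 1/lam — a mild penalty), SVM
cost `C = 1.0`, polynomial kernel fixed at degree 2 with `gamma = 1`,
`coef0 = 0` (a plain (x·y)² kernel), naive Bayes smoothing `alpha = 1.0`,
100 SGD epochs, tree minimum leaf size 2. No tuning loop exists because
none is part of the method. The naive Bayes accepts real-valued
nonnegative features so TF-IDF inputs are legal. The decision tree uses
the entropy criterion — the CART analogue of the classic gain-ratio
tree; exact gain-ratio/pruning semantics of the original C4.5 are not
reproduced.

## Evaluation

Metrics come from the pooled confusion matrix with *nano* positive.
The reporting default is support-weighted averaging of the two per-class
views, the workbench convention under which a balanced corpus's weighted
TP rate equals overall accuracy. On balanced true classes the expected
chance agreement of Cohen's kappa is exactly ½ for *any* prediction
marginals, giving the identity kappa = 2·accuracy − 1; this is checked
symbolically in a property test and is the arithmetic linking printed TP
rates (e.g. 0.955) to printed kappas (0.91). MCC and kappa return 0 on
degenerate denominators. AUC is the rank-based Mann-Whitney statistic
with mid-rank tie correction; ROC points are emitted at every distinct
threshold.

Stratified k-fold shuffles each class independently under the run seed
and deals near-equal chunks, so per-fold class proportions match the
corpus to within one document (exactly 50/50 folds of 100 for the
balanced-1000 case). 10-fold reports per-fold metrics, their mean and
SEM = sd(fold values, ddof=1)/√k. LOO pools all n held-out predictions
into a single confusion matrix — per-instance rates are undefined, so no
SEM is reported. Self-consistency trains and tests on the full corpus as
an optimistic stability reference. The learning curve draws a freshly
randomized stratified split per fraction (default grid 0.10 … 0.90,
0.95) and reports accuracy on the complement.

## Synthetic corpora

The generator emulates the curated registry corpus as study conditions:
balanced classes (default 500 + 500), heavy-tailed document lengths from
a log-normal parameterized to mean 732 / sd 1000 tokens and floored at
111 (the length profile reported for real trial summaries), a Zipfian
background vocabulary (2000 types, exponent 1.1) giving realistic df
skew, and 20 class-specific terms per class injected per *token* at rate
0.05 (cross-class bleed 0 by default). Token-level injection keeps
discriminative terms sparse within documents, matching how nano
terminology appears as scattered single-token modifiers in real
summaries. All generated tokens are lowercase, vowel-free, length ≥ 3
and Porter fixed points, so the preprocessing chain is a near-no-op on
them and ground-truth terms can be compared directly with learned
weights. Identical seeds give byte-identical corpora.

Benchmarks built on it, at the sizes the package uses throughout
(n_per_class = 100, i.e. 200-document LOO runs):

- a *null* corpus (equal injection and cross rates, hence identical
  class-conditional distributions in expectation) must give LOO AUC in
  [0.40, 0.60];
- the injected-signal corpus must reach LOO AUC ≥ 0.90 for the lasso +
  IDF pipeline with at least half of the ten largest-|weight| features
  being ground-truth class terms;
- AUC must be monotone (one ≤ 0.02 inversion allowed) in injection rate
  over {0, 0.01, 0.03, 0.05, 0.1};
- learning-curve accuracy must correlate positively with training
  fraction. For this check the corpus uses a *weak* signal (injection
  0.005): at 5% injection the classifier is already perfect with 10% of
  the data and the curve is flat at 1.0, which is uninformative about
  training-size effects.

What passing these does **not** show: the generator produces no clinical
prose, no bigram dependence structure, no synonymy or spelling variation,
and its class signal is cleanly injected rather than entangled with
topic. Absolute performance figures on real registry text (e.g. LOO TP
rate 0.955 on the curated 1000-trial corpus) therefore cannot be
reproduced from synthetic data; the package instead verifies the exact
metric arithmetic those figures rest on, plus signal detection and
recovery under controlled conditions.

## Numerical choices and degenerate inputs

- idf uses base e; the log base only rescales linear-model inputs.
- All-zero document rows are left as zero vectors by normalization.
- Score ties at the decision threshold predict *nano* (stated once,
  tested).
- MCC/kappa: 0 on degenerate denominators; metrics on an empty confusion
  matrix raise.
- `stratified_kfold` raises if k exceeds the smallest class count;
  learning-curve fractions leaving less than one document per class in
  train or test raise.
- Seeds: every stochastic component (fold shuffling, SGD, tree
  tie-breaking, corpus generation) takes an explicit integer seed;
  repeated runs are bit-reproducible.

## Known limitations

- The registry's "textual content" field set is not canonical; the
  default field list is a documented choice and configurable.
- The stop-word list membership is a package choice (standard English
  function words); results depend mildly on it.
- The decision-tree family approximates, not reproduces, classic C4.5.
- Retrieval matches the assembled text rather than per-field, so field
  provenance of a match is not reported.
- MNB with strongly non-integral features is a heuristic use of the
  multinomial likelihood (useful in practice for TF-IDF inputs).
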