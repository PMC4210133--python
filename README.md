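# nanoct

Supervised classification of clinical-trial registry summaries as **nano**
(the trial tests a nanodrug, nanoparticle formulation or nanodevice) versus
**non-nano** (a conventional intervention).

Public registries such as ClinicalTrials.gov do not distinguish trials of
nanotechnology-based products from conventional ones, and the lack of a
consensus "nano" definition makes even expert annotation slow and
inconsistent. `nanoct` implements the full text-mining pipeline needed to
learn that distinction from the free-text summary of a registered study:

- **ctgov_io** — parse study-record XML (one NCT-identified record per
  trial) into newline-joined free text; read/write CSV label tables and
  JSON-lines corpora.
- **retrieval** — match curated concept/synonym term lists against a local
  corpus (whole-token, phrase and prefix modes) to propose nano candidates
  for human review.
- **preprocess** — tokenize on non-alphanumerics, mask digits with `#`,
  lowercase, drop stop words and tokens shorter than three characters,
  Porter-stem; count unigram/bigram bags per document.
- **vectorize** — sparse document–feature matrices under four weightings:
  binary, term frequency, IDF and TF-IDF, with idf(t) = ln(N/df(t)) and
  optional L2 row normalization.
- **classify** — seven classifier families behind one contract:
  multinomial naive Bayes, an entropy-criterion decision tree, SGD
  logistic regression, lasso (L1) and ridge (L2) logistic regression, and
  linear / degree-2 polynomial SVMs.
- **evaluate** — stratified 10-fold CV, leave-one-out and self-consistency
  validation with the vocabulary refit inside every training split;
  TP/FP rate, precision, recall, F, Matthews correlation, Cohen's kappa,
  rank-based AUC, fold-wise SEM, and learning curves.
- **synthetic** — a generator of balanced pseudo-trial corpora with
  heavy-tailed document lengths and sparsely injected class-specific
  terms, so the whole pipeline is testable without downloads.

The statistical core: each document *d* is a sparse bag-of-words vector
x(d) with components w(t, d) ∈ {1[t ∈ d], tf(t, d), ln(N/df(t))·1[t ∈ d],
tf(t, d)·ln(N/df(t))}, and the reference classifier is L1-regularized
logistic regression, min<sub>w,b</sub> Σ log(1 + e<sup>−y(w·x+b)</sup>) +
λ‖w‖₁, whose sparsity doubles as feature selection over the ~10⁴-feature
vocabulary. On a class-balanced corpus Cohen's kappa reduces exactly to
2·accuracy − 1, which ties the printed agreement statistics to the TP
rates.

## Worked example

```python
from nanoct import (ClassifierSpec, GeneratorConfig, corpus_to_bags,
                    generate, run_validation)

sc = generate(GeneratorConfig(n_per_class=100, injection_rate=0.01, seed=42))
bags = corpus_to_bags(sc.corpus.texts)
spec = ClassifierSpec(family="l1_logreg", seed=0)
for mode in ("kfold", "loo", "self_consistency"):
    rep = run_validation(bags, sc.corpus.labels, "idf", spec, mode=mode, seed=0)
    print(mode, rep.pooled)
```

prints (see `examples/05_cross_validation.py`):

```
           kfold: TPR 0.960  FPR 0.040  P 0.960  R 0.960  F 0.960  MCC 0.920  kappa 0.920  AUC 0.992  (SEM of fold TPR 0.0194)
             loo: TPR 0.970  FPR 0.030  P 0.970  R 0.970  F 0.970  MCC 0.940  kappa 0.940  AUC 0.995
self_consistency: TPR 1.000  FPR 0.000  P 1.000  R 1.000  F 1.000  MCC 1.000  kappa 1.000  AUC 1.000
```

The corpus here is synthetic: 200 balanced documents whose classes differ
only through 20 class-specific terms injected at 1% per token. The lasso
+ IDF pipeline recovers the signal almost perfectly (kappa 0.92 under
10-fold CV, i.e. 96% accuracy on the balanced corpus); self-consistency
(train = test) is the optimistic stability reference. The `examples/`
directory has one short script per capability: record parsing, dictionary
retrieval, preprocessing statistics, the four weighting schemes,
cross-validation and the learning curve.

A thin CLI mirrors the library:

```bash
nanoct synth --n-per-class 100 --seed 3 --out corpus.jsonl
nanoct evaluate --corpus corpus.jsonl --scheme idf --family l1_logreg \
    --modes kfold,loo --report out/
nanoct retrieve --corpus corpus.jsonl --terms terms.tsv --mode prefix \
    --out matches.json
```

## Limitations

Term lists are consumed as plain files (no terminology-service access),
live registry search is out of scope, and the synthetic generator makes
no attempt at realistic clinical prose — see `docs/methods.md` for what
the synthetic benchmarks do and do not establish about real registry
data.
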