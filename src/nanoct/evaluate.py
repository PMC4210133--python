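"""Validation harness and metric suite.

Implements stratified k-fold cross-validation, leave-one-out (LOO) and
self-consistency evaluation over the bag-of-words pipeline, with the
vectorization (vocabulary, df, idf) refit inside every training split so
no document-frequency information leaks from held-out documents.

Metrics are computed from the confusion matrix with ``nano`` as the
positive class.  The reporting default is support-weighted averaging over
the two classes, which on a balanced corpus makes the weighted TP rate
equal overall accuracy and ties it to Cohen's kappa through the identity
kappa = 2*accuracy - 1 (expected chance agreement is exactly 1/2 whenever
the true classes are balanced, regardless of the prediction marginals).
Degenerate denominators in precision/recall/F, MCC and kappa yield 0.

AUC is the rank-based (Mann-Whitney) statistic with mid-rank tie
correction; ROC points are emitted at every distinct score threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.stats import rankdata

from .classify import ClassifierSpec, TrainedModel, predict, score, train
from .preprocess import NGramBag
from .vectorize import _apply_scheme, _count_matrix, Vocabulary, build_vocabulary

__all__ = [
    "ConfusionMatrix", "MetricSet", "EvaluationReport",
    "stratified_kfold", "confusion_metrics", "per_class_metrics",
    "roc_auc", "run_validation", "learning_curve", "split_weight_matrices",
]

POSITIVE = "nano"


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with nano as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)

    @classmethod
    def from_predictions(cls, y_true: Sequence[str], y_pred: Sequence[str],
                         positive: str = POSITIVE) -> "ConfusionMatrix":
        tp = fp = tn = fn = 0
        for t, p in zip(y_true, y_pred, strict=True):
            if t == positive:
                tp, fn = (tp + 1, fn) if p == positive else (tp, fn + 1)
            else:
                fp, tn = (fp + 1, tn) if p == positive else (fp, tn + 1)
        return cls(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass(frozen=True)
class MetricSet:
    tpr: float
    fpr: float
    precision: float
    recall: float
    f_measure: float
    mcc: float
    kappa: float
    accuracy: float
    auc: float | None = None
    averaging: str = "weighted"

    def as_dict(self) -> dict:
        return asdict(self)


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def per_class_metrics(cm: ConfusionMatrix) -> dict[str, dict[str, float]]:
    """TPR/FPR/precision/recall/F treating each class in turn as positive."""
    out = {}
    for cls, (tp, fp, tn, fn) in {
        "positive": (cm.tp, cm.fp, cm.tn, cm.fn),
        "negative": (cm.tn, cm.fn, cm.tp, cm.fp),
    }.items():
        recall = _safe_div(tp, tp + fn)
        precision = _safe_div(tp, tp + fp)
        out[cls] = {
            "tpr": recall,
            "fpr": _safe_div(fp, fp + tn),
            "precision": precision,
            "recall": recall,
            "f_measure": _safe_div(2 * precision * recall, precision + recall),
            "support": tp + fn,
        }
    return out


def _mcc(cm: ConfusionMatrix) -> float:
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def _kappa(cm: ConfusionMatrix) -> float:
    n = cm.total
    po = (cm.tp + cm.tn) / n
    pe = ((cm.tp + cm.fp) * (cm.tp + cm.fn)
          + (cm.fn + cm.tn) * (cm.fp + cm.tn)) / (n * n)
    if pe == 1.0:
        return 0.0
    return (po - pe) / (1 - pe)


def confusion_metrics(cm: ConfusionMatrix,
                      averaging: str = "weighted") -> MetricSet:
    """Metric set (without AUC) from one confusion matrix.

    ``weighted`` combines the two per-class views by true-class support —
    the convention under which the printed TP rate of a balanced corpus is
    the overall accuracy.  ``positive`` reports the nano-class view only.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    if averaging not in ("weighted", "positive"):
        raise ValueError("averaging must be 'weighted' or 'positive'")
    per = per_class_metrics(cm)
    if averaging == "positive":
        sel = per["positive"]
        vals = {k: sel[k] for k in ("tpr", "fpr", "precision", "recall",
                                    "f_measure")}
    else:
        n = cm.total
        vals = {
            k: sum(per[c][k] * per[c]["support"] for c in per) / n
            for k in ("tpr", "fpr", "precision", "recall", "f_measure")
        }
    return MetricSet(
        **vals,
        mcc=_mcc(cm),
        kappa=_kappa(cm),
        accuracy=(cm.tp + cm.tn) / cm.total,
        averaging=averaging,
    )


def roc_auc(scores: Sequence[float], labels: Sequence[str],
            positive: str = POSITIVE) -> tuple[float, list[tuple[float, float, float]]]:
    """Rank-based AUC with mid-rank tie correction, plus ROC points.

    Returns ``(auc, points)`` where points are (fpr, tpr, threshold)
    triples at every distinct score, from the most permissive threshold to
    the strictest, bracketed by (0, 0) and (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = y == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(scores)  # mid-ranks for ties
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="stable")
    points: list[tuple[float, float, float]] = [(0.0, 0.0, math.inf)]
    tp = fp = 0
    sorted_scores = scores[order]
    sorted_pos = pos[order]
    i = 0
    while i < len(scores):
        thr = sorted_scores[i]
        while i < len(scores) and sorted_scores[i] == thr:
            if sorted_pos[i]:
                tp += 1
            else:
                fp += 1
            i += 1
        points.append((fp / n_neg, tp / n_pos, float(thr)))
    return float(auc), points


# ---------------------------------------------------------------------------
# splitting


def stratified_kfold(labels: Sequence[str], k: int = 10,
                     seed: int = 0) -> list[np.ndarray]:
    """k disjoint test-index sets with per-fold class proportions matching
    the corpus to within one document; deterministic under ``seed``."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > counts.min():
        raise ValueError(
            f"k={k} exceeds the smallest class count ({counts.min()})"
        )
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in classes:
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for j, chunk in enumerate(np.array_split(idx, k)):
            folds[j].extend(chunk.tolist())
    return [np.array(sorted(f), dtype=int) for f in folds]


def split_weight_matrices(
    bags: Sequence[NGramBag],
    train_idx: Sequence[int],
    test_idx: Sequence[int],
    scheme: str,
    normalized: bool = False,
) -> tuple[sp.csr_matrix, sp.csr_matrix, Vocabulary]:
    """Vectorize one train/test split with the vocabulary refit on the
    training documents only.

    The returned matrices are restricted to features whose training df is
    at least 1, so a feature occurring only in test documents has no
    column at all (the no-leakage guarantee).  Implemented over a
    precomputed global count matrix for speed; equivalent to rebuilding
    the vocabulary from the training bags.
    """
    global_vocab = build_vocabulary(bags)
    index = global_vocab.index()
    C = _count_matrix(bags, index, len(global_vocab))
    return _split_from_counts(C, np.array(global_vocab.features),
                              train_idx, test_idx, scheme, normalized)


def _presence(C: sp.csr_matrix) -> sp.csr_matrix:
    P = C.copy()
    P.data = np.ones_like(P.data)
    return P


def _split_from_counts(C, feature_names, train_idx, test_idx, scheme,
                       normalized):
    train_idx = np.asarray(train_idx, dtype=int)
    test_idx = np.asarray(test_idx, dtype=int)
    P = _presence(C)
    df = np.asarray(P[train_idx].sum(axis=0)).ravel()
    keep = df > 0
    kept_names = feature_names[keep]
    kept_df = df[keep].astype(int)
    vocab = Vocabulary(
        features=tuple(kept_names),
        df=dict(zip(kept_names.tolist(), kept_df.tolist())),
        N=len(train_idx),
    )
    Ctr = C[train_idx][:, keep]
    Cte = C[test_idx][:, keep]
    Xtr = _apply_scheme(Ctr.tocsr(), vocab, scheme, normalized)
    Xte = _apply_scheme(Cte.tocsr(), vocab, scheme, normalized)
    return Xtr, Xte, vocab


@dataclass
class EvaluationReport:
    mode: str                        # kfold | loo | self_consistency
    scheme: str
    normalized: bool
    spec: ClassifierSpec
    seed: int
    pooled: MetricSet
    confusion: ConfusionMatrix
    per_fold: list[MetricSet] | None = None
    sem: dict[str, float] | None = None
    fold_assignment: list[list[int]] | None = None

    def as_dict(self) -> dict:
        return {
            "mode": self.mode,
            "scheme": self.scheme,
            "normalized": self.normalized,
            "family": self.spec.family,
            "seed": self.seed,
            "pooled": self.pooled.as_dict(),
            "confusion": asdict(self.confusion),
            "per_fold": [m.as_dict() for m in self.per_fold]
            if self.per_fold is not None else None,
            "sem": self.sem,
            "fold_assignment": [list(map(int, f)) for f in self.fold_assignment]
            if self.fold_assignment is not None else None,
        }


def _metrics_with_auc(cm, scores, labels, averaging="weighted") -> MetricSet:
    base = confusion_metrics(cm, averaging=averaging)
    try:
        auc, _ = roc_auc(scores, labels)
    except ValueError:
        auc = None
    return MetricSet(**{**base.as_dict(), "auc": auc})


_SEM_KEYS = ("tpr", "fpr", "precision", "recall", "f_measure", "mcc",
             "kappa", "accuracy", "auc")


def run_validation(
    bags: Sequence[NGramBag],
    labels: Sequence[str],
    scheme: str,
    spec: ClassifierSpec,
    mode: str = "kfold",
    seed: int = 0,
    normalized: bool = False,
    k: int = 10,
) -> EvaluationReport:
    """Evaluate one (scheme, classifier) pipeline configuration.

    ``kfold`` reports per-fold metrics, their mean's standard error
    (SEM = sample sd of fold values / sqrt(k)) and the pooled confusion
    matrix; ``loo`` pools all n held-out predictions into one confusion
    matrix (per-instance folds have no defined rates); and
    ``self_consistency`` trains and tests on the full corpus.
    """
    y = np.asarray(labels)
    vocab_all = build_vocabulary(bags)
    C = _count_matrix(bags, vocab_all.index(), len(vocab_all))
    names = np.array(vocab_all.features)

    def fit_split(train_idx, test_idx):
        Xtr, Xte, _ = _split_from_counts(C, names, train_idx, test_idx,
                                         scheme, normalized)
        model = train(Xtr, y[train_idx], spec)
        return predict(model, Xte), score(model, Xte)

    if mode == "kfold":
        folds = stratified_kfold(labels, k=k, seed=seed)
        all_idx = np.arange(len(y))
        per_fold, cms, all_scores, all_true, all_pred = [], [], [], [], []
        for test_idx in folds:
            train_idx = np.setdiff1d(all_idx, test_idx)
            y_pred, s = fit_split(train_idx, test_idx)
            cm = ConfusionMatrix.from_predictions(y[test_idx], y_pred)
            cms.append(cm)
            per_fold.append(_metrics_with_auc(cm, s, y[test_idx]))
            all_scores.extend(s)
            all_true.extend(y[test_idx])
            all_pred.extend(y_pred)
        pooled_cm = sum(cms[1:], cms[0])
        pooled = _metrics_with_auc(pooled_cm, all_scores, all_true)
        sem = {}
        for key in _SEM_KEYS:
            vals = [getattr(m, key) for m in per_fold]
            if any(v is None for v in vals):
                continue
            sem[key] = float(np.std(vals, ddof=1) / math.sqrt(len(vals)))
        return EvaluationReport(
            mode=mode, scheme=scheme, normalized=normalized, spec=spec,
            seed=seed, pooled=pooled, confusion=pooled_cm, per_fold=per_fold,
            sem=sem, fold_assignment=[f.tolist() for f in folds],
        )

    if mode == "loo":
        n = len(y)
        all_idx = np.arange(n)
        preds = np.empty(n, dtype=object)
        scores_out = np.empty(n, dtype=float)
        for i in range(n):
            train_idx = np.delete(all_idx, i)
            y_pred, s = fit_split(train_idx, np.array([i]))
            preds[i] = y_pred[0]
            scores_out[i] = s[0]
        cm = ConfusionMatrix.from_predictions(y, preds)
        pooled = _metrics_with_auc(cm, scores_out, y)
        return EvaluationReport(mode=mode, scheme=scheme, normalized=normalized,
                                spec=spec, seed=seed, pooled=pooled,
                                confusion=cm)

    if mode == "self_consistency":
        all_idx = np.arange(len(y))
        y_pred, s = fit_split(all_idx, all_idx)
        cm = ConfusionMatrix.from_predictions(y, y_pred)
        pooled = _metrics_with_auc(cm, s, y)
        return EvaluationReport(mode=mode, scheme=scheme, normalized=normalized,
                                spec=spec, seed=seed, pooled=pooled,
                                confusion=cm)

    raise ValueError(f"unknown mode {mode!r}")


DEFAULT_FRACTIONS = (0.10, 0.20, 0.30, 0.40, 0.50, 0.60, 0.70, 0.80, 0.90, 0.95)


def learning_curve(
    bags: Sequence[NGramBag],
    labels: Sequence[str],
    scheme: str,
    spec: ClassifierSpec,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    seed: int = 0,
    normalized: bool = False,
) -> list[dict]:
    """Accuracy on the complementary test set per training fraction.

    Each fraction gets a freshly randomized stratified split (derived from
    ``seed``); the default grid grows the training set from 10% to 95% of
    the corpus.
    """
    fr = list(fractions)
    if any(not 0 < f < 1 for f in fr) or any(b <= a for a, b in zip(fr, fr[1:])):
        raise ValueError("fractions must be strictly increasing within (0, 1)")
    y = np.asarray(labels)
    classes = np.unique(y)
    vocab_all = build_vocabulary(bags)
    C = _count_matrix(bags, vocab_all.index(), len(vocab_all))
    names = np.array(vocab_all.features)

    results = []
    for j, f in enumerate(fr):
        rng = np.random.default_rng([seed, j])
        train_idx: list[int] = []
        for cls in classes:
            idx = np.flatnonzero(y == cls)
            n_train = int(round(f * len(idx)))
            if n_train < 1 or n_train >= len(idx):
                raise ValueError(
                    f"fraction {f} leaves <1 document per class in train or test"
                )
            rng.shuffle(idx)
            train_idx.extend(idx[:n_train].tolist())
        train_idx = np.array(sorted(train_idx))
        test_idx = np.setdiff1d(np.arange(len(y)), train_idx)
        Xtr, Xte, _ = _split_from_counts(C, names, train_idx, test_idx,
                                         scheme, normalized)
        model = train(Xtr, y[train_idx], spec)
        y_pred = predict(model, Xte)
        acc = float((y_pred == y[test_idx]).mean())
        results.append({"fraction": f, "n_train": int(len(train_idx)),
                        "n_test": int(len(test_idx)), "accuracy": acc})
    return results
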