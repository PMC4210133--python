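"""Bag-of-words weighting: vocabulary, df, and the four representations.

Schemes, for document d and feature t with term frequency tf(t, d),
document frequency df(t) over the N training documents:

``binary``      1 if t occurs in d else 0
``frequency``   tf(t, d)
``idf``         idf(t) if t occurs in d else 0, with idf(t) = ln(N / df(t))
``tfidf``       tf(t, d) * idf(t)

idf uses the unsmoothed natural log so a feature present in every
training document gets weight exactly 0 — it carries no class signal and
vanishes from the idf/tfidf representations.  Optional L2 normalization
scales each nonzero document row to unit Euclidean norm.

Vocabulary order is lexicographic so matrices are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .preprocess import NGramBag

__all__ = ["Vocabulary", "DocTermMatrix", "SCHEMES", "build_vocabulary",
           "weight", "apply_vocabulary"]

SCHEMES = ("binary", "frequency", "idf", "tfidf")


@dataclass(frozen=True)
class Vocabulary:
    features: tuple[str, ...]          # lexicographically sorted, unique
    df: dict[str, int]                 # feature -> number of docs containing it
    N: int                             # training corpus size

    def __post_init__(self) -> None:
        for t, d in self.df.items():
            if not 1 <= d <= self.N:
                raise ValueError(f"df out of range for {t!r}: {d} (N={self.N})")

    def __len__(self) -> int:
        return len(self.features)

    def index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.features)}

    def idf_vector(self) -> np.ndarray:
        df = np.array([self.df[t] for t in self.features], dtype=float)
        return np.log(self.N / df)


@dataclass
class DocTermMatrix:
    matrix: sp.csr_matrix              # documents x features, entries >= 0
    scheme: str
    normalized: bool
    vocabulary: Vocabulary

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


def build_vocabulary(bags: Sequence[NGramBag]) -> Vocabulary:
    """Union of all bag features, sorted; df counted by presence."""
    if not bags:
        raise ValueError("empty corpus")
    df: dict[str, int] = {}
    for bag in bags:
        for t in bag.counts:
            df[t] = df.get(t, 0) + 1
    return Vocabulary(features=tuple(sorted(df)), df=df, N=len(bags))


def _count_matrix(bags: Sequence[NGramBag], index: dict[str, int],
                  n_features: int) -> sp.csr_matrix:
    """Raw tf matrix; features outside the vocabulary are dropped."""
    data, indices, indptr = [], [], [0]
    for bag in bags:
        cols = sorted(
            (index[t], c) for t, c in bag.counts.items() if t in index
        )
        indices.extend(i for i, _ in cols)
        data.extend(c for _, c in cols)
        indptr.append(len(indices))
    return sp.csr_matrix(
        (np.array(data, dtype=float), indices, indptr),
        shape=(len(bags), n_features),
    )


def _apply_scheme(tf: sp.csr_matrix, vocab: Vocabulary, scheme: str,
                  normalized: bool) -> sp.csr_matrix:
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    X = tf.copy()
    if scheme == "binary":
        X.data = np.ones_like(X.data)
    elif scheme == "idf":
        X.data = np.ones_like(X.data)
        X = X.multiply(vocab.idf_vector()).tocsr()
    elif scheme == "tfidf":
        X = X.multiply(vocab.idf_vector()).tocsr()
    if normalized:
        norms = np.sqrt(np.asarray(X.multiply(X).sum(axis=1)).ravel())
        inv = np.divide(1.0, norms, out=np.zeros_like(norms), where=norms > 0)
        X = sp.diags(inv) @ X
    X.eliminate_zeros()
    return X.tocsr()


def weight(bags: Sequence[NGramBag], vocab: Vocabulary, scheme: str,
           normalized: bool = False) -> DocTermMatrix:
    """Weight training bags against their own vocabulary."""
    tf = _count_matrix(bags, vocab.index(), len(vocab))
    return DocTermMatrix(
        matrix=_apply_scheme(tf, vocab, scheme, normalized),
        scheme=scheme,
        normalized=normalized,
        vocabulary=vocab,
    )


def apply_vocabulary(bags: Sequence[NGramBag] | NGramBag, vocab: Vocabulary,
                     scheme: str, normalized: bool = False) -> sp.csr_matrix:
    """Vectorize held-out documents with a training vocabulary.

    Uses the training N and df; features unseen in training are ignored.
    Accepts one bag or a sequence; always returns a 2-D sparse matrix.
    """
    if isinstance(bags, NGramBag):
        bags = [bags]
    tf = _count_matrix(bags, vocab.index(), len(vocab))
    return _apply_scheme(tf, vocab, scheme, normalized)
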