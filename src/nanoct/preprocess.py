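"""Text normalization and n-gram feature extraction.

The pipeline converts raw record text into normalized token streams in a
fixed order:

1. split into tokens on any character that is not alphanumeric or
   underscore;
2. replace every decimal digit with ``'#'``;
3. lowercase;
4. drop stop words;
5. drop tokens shorter than three characters;
6. Porter-stem the survivors.

The digit mask runs before the length filter, so a masked number such as
``"100" -> "###"`` survives (length 3).  Stemming runs last, so stems may
legitimately be shorter than three characters.  Unigram and bigram bags
are counted per document; bigrams never cross newline boundaries because
newlines separate unrelated record fields.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .porter import porter_stem

__all__ = [
    "TokenStream",
    "NGramBag",
    "BIGRAM_SEP",
    "load_stopwords",
    "tokenize",
    "normalize",
    "extract_ngrams",
    "text_to_bag",
    "corpus_to_bags",
    "corpus_feature_stats",
]

#: Joins the two tokens of a bigram feature; a newline can never appear
#: inside a token, so features are unambiguous.
BIGRAM_SEP = "\n"

_DIGIT_TABLE = str.maketrans("0123456789", "##########")


@dataclass(frozen=True)
class TokenStream:
    tokens: tuple[str, ...]
    stage: str  # "raw" | "normalized"


@dataclass(frozen=True)
class NGramBag:
    n: int
    counts: dict[str, int]


def load_stopwords(path: str | Path | None = None) -> frozenset[str]:
    """Load a stop-word list (one word per line, '#' comments allowed).

    With no argument, returns the frozen English list shipped with the
    package.
    """
    if path is None:
        text = (
            resources.files("nanoct.data")
            .joinpath("stopwords_en.txt")
            .read_text(encoding="utf-8")
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    words = set()
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.add(line.lower())
    return frozenset(words)


_DEFAULT_STOPWORDS = None


def default_stopwords() -> frozenset[str]:
    global _DEFAULT_STOPWORDS
    if _DEFAULT_STOPWORDS is None:
        _DEFAULT_STOPWORDS = load_stopwords()
    return _DEFAULT_STOPWORDS


def tokenize(text: str) -> TokenStream:
    """Split text into raw tokens.

    Tokens are maximal runs of alphanumeric-or-underscore characters;
    every other character (whitespace, punctuation, hyphens) separates
    tokens.  Newlines are preserved as the sentinel token ``"\\n"`` so the
    n-gram stage can respect field boundaries.
    """
    tokens: list[str] = []
    current: list[str] = []
    for ch in text:
        if ch.isalnum() or ch == "_":
            current.append(ch)
        else:
            if current:
                tokens.append("".join(current))
                current = []
            if ch == "\n":
                tokens.append("\n")
    if current:
        tokens.append("".join(current))
    return TokenStream(tuple(tokens), stage="raw")


def normalize(
    stream: TokenStream,
    stopwords: frozenset[str] | None = None,
) -> TokenStream:
    """Apply the fixed normalization pipeline to a raw token stream.

    Order: digit mask, lowercase, stop-word removal, length >= 3 filter,
    Porter stemming.  Newline sentinels pass through untouched.
    """
    if stopwords is None:
        stopwords = default_stopwords()
    out: list[str] = []
    for tok in stream.tokens:
        if tok == "\n":
            out.append(tok)
            continue
        tok = tok.translate(_DIGIT_TABLE).lower()
        if tok in stopwords:
            continue
        if len(tok) < 3:
            continue
        out.append(porter_stem(tok))
    return TokenStream(tuple(out), stage="normalized")


def extract_ngrams(stream: TokenStream, n: int) -> NGramBag:
    """Count unigrams (n=1) or adjacent-pair bigrams (n=2) in one document.

    Bigrams are ordered pairs of adjacent tokens joined by
    :data:`BIGRAM_SEP`; pairs never span a newline sentinel.
    """
    if n not in (1, 2):
        raise ValueError("n must be 1 or 2")
    counts: Counter[str] = Counter()
    if n == 1:
        counts.update(t for t in stream.tokens if t != "\n")
    else:
        toks = stream.tokens
        for a, b in zip(toks, toks[1:]):
            if a != "\n" and b != "\n":
                counts[a + BIGRAM_SEP + b] += 1
    return NGramBag(n=n, counts=dict(counts))


def text_to_bag(
    text: str,
    n: int = 1,
    stopwords: frozenset[str] | None = None,
) -> NGramBag:
    """Full pipeline for one document: tokenize, normalize, count n-grams."""
    return extract_ngrams(normalize(tokenize(text), stopwords), n)


def corpus_to_bags(
    texts: Iterable[str],
    n: int = 1,
    stopwords: frozenset[str] | None = None,
) -> list[NGramBag]:
    return [text_to_bag(t, n=n, stopwords=stopwords) for t in texts]


def corpus_feature_stats(bags: Sequence[NGramBag]) -> dict:
    """Per-corpus feature statistics.

    Returns per-document totals (with and without double-counting), their
    min/max/mean/sd (population sd), the global distinct-feature count,
    per-feature document frequencies and the mean number of documents per
    feature.
    """
    if not bags:
        raise ValueError("empty corpus")
    totals = [sum(b.counts.values()) for b in bags]
    uniques = [len(b.counts) for b in bags]
    df: Counter[str] = Counter()
    for b in bags:
        df.update(b.counts.keys())

    def _summary(values: list[int]) -> dict:
        mean = sum(values) / len(values)
        var = sum((v - mean) ** 2 for v in values) / len(values)
        return {
            "min": min(values),
            "max": max(values),
            "mean": mean,
            "sd": math.sqrt(var),
        }

    n_features = len(df)
    return {
        "n_documents": len(bags),
        "per_document_total": _summary(totals),
        "per_document_unique": _summary(uniques),
        "n_features": n_features,
        "document_frequency": dict(df),
        "mean_docs_per_feature": sum(df.values()) / n_features,
    }
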