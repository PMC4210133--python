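"""Dictionary-based candidate retrieval.

Matches curated term/synonym lists (e.g. concepts exported from a
biomedical metathesaurus) against corpus text to propose records that
look nano-related, for human review.  Matching runs on the raw
case-folded surface token stream — before digit masking, stop-word
removal or stemming — because dictionary terms are surface forms.
Hyphens and other punctuation act as token separators, so matching is
invariant to surrounding punctuation.

Three modes:

``token``
    every token of the (possibly multiword) term must match a whole
    corpus token, contiguously for multiword terms;
``phrase``
    alias semantics for multiword terms — contiguous whole-token match
    (for a one-token term, identical to ``token``);
``prefix``
    the last term token may match any corpus token that merely begins
    with it (the capability public registry search engines typically
    lack); earlier tokens of a multiword term must match exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .ctgov_io import LabeledCorpus
from .preprocess import tokenize

__all__ = [
    "TermList",
    "MatchReport",
    "load_term_list",
    "match_terms",
    "propose_candidates",
]

MODES = ("token", "phrase", "prefix")


@dataclass(frozen=True)
class TermList:
    """Concepts with their synonym terms: list of (concept_id, terms)."""

    concepts: tuple[tuple[str, tuple[str, ...]], ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        for cid, terms in self.concepts:
            if not terms or any(not t.strip() for t in terms):
                raise ValueError(f"concept {cid!r} has empty terms")

    @property
    def n_concepts(self) -> int:
        return len(self.concepts)

    @property
    def n_terms(self) -> int:
        return sum(len(t) for _, t in self.concepts)


@dataclass
class MatchReport:
    """Match results over a corpus.

    ``per_record`` maps record id -> list of (concept_id, term, count)
    with count > 0; records without matches are absent.
    """

    per_record: dict[str, list[tuple[str, str, int]]]
    n_records_scanned: int

    @property
    def matched_record_ids(self) -> set[str]:
        return set(self.per_record)

    @property
    def matched_concepts(self) -> set[str]:
        return {cid for hits in self.per_record.values() for cid, _, _ in hits}

    def concepts_per_record(self) -> dict[str, int]:
        return {
            rid: len({cid for cid, _, _ in hits})
            for rid, hits in self.per_record.items()
        }


def load_term_list(path: str | Path, provenance: str = "") -> TermList:
    """Read a UTF-8 ``concept_id<TAB>term`` file (synonyms share an id)."""
    concepts: dict[str, list[str]] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cid, _, term = line.partition("\t")
        if not term.strip():
            raise ValueError(f"malformed term-list line: {line!r}")
        concepts.setdefault(cid.strip(), []).append(term.strip())
    return TermList(
        concepts=tuple((cid, tuple(ts)) for cid, ts in concepts.items()),
        provenance=provenance or str(path),
    )


def _surface_tokens(text: str) -> list[str]:
    return [t.lower() for t in tokenize(text).tokens if t != "\n"]


def _count_matches(doc: list[str], term_tokens: list[str], prefix: bool) -> int:
    k = len(term_tokens)
    if k == 0 or len(doc) < k:
        return 0
    count = 0
    head, last = term_tokens[:-1], term_tokens[-1]
    for i in range(len(doc) - k + 1):
        if doc[i : i + k - 1] != head:
            continue
        tok = doc[i + k - 1]
        if tok.startswith(last) if prefix else tok == last:
            count += 1
    return count


def match_terms(
    corpus: LabeledCorpus | Sequence,
    terms: TermList,
    mode: str = "token",
) -> MatchReport:
    """Match every term of every concept against every record.

    Accepts a :class:`LabeledCorpus` or any sequence of objects with
    ``nct_id`` and ``text`` attributes.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if terms.n_concepts == 0:
        raise ValueError("empty term list")
    records = corpus.records if isinstance(corpus, LabeledCorpus) else list(corpus)

    per_record: dict[str, list[tuple[str, str, int]]] = {}
    for rec in records:
        doc = _surface_tokens(rec.text)
        hits: list[tuple[str, str, int]] = []
        for cid, synonyms in terms.concepts:
            for term in synonyms:
                term_tokens = [t.lower() for t in tokenize(term).tokens if t != "\n"]
                c = _count_matches(doc, term_tokens, prefix=(mode == "prefix"))
                if c > 0:
                    hits.append((cid, term, c))
        if hits:
            per_record[rec.nct_id] = hits
    return MatchReport(per_record=per_record, n_records_scanned=len(records))


def propose_candidates(report: MatchReport, min_concepts: int = 1) -> set[str]:
    """Record ids with at least ``min_concepts`` distinct matched concepts."""
    return {
        rid
        for rid, n in report.concepts_per_record().items()
        if n >= min_concepts
    }
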