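"""Reading and writing ClinicalTrials.gov study records and label tables.

A study record is a single XML document identified by an NCT accession
("NCT" followed by eight digits).  The free-text fields of the record are
concatenated into one text blob per trial; a label table maps NCT ids to
the two classes (by default ``nano`` / ``non-nano``).  Corpora are stored
on disk either as a directory of XML records plus a CSV label table, or as
JSON-lines (one object per record) for downstream stages.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from lxml import etree

__all__ = [
    "CTRecord",
    "LabeledCorpus",
    "DEFAULT_FIELD_CONFIG",
    "DEFAULT_LABELS",
    "parse_ct_record",
    "load_label_table",
    "assemble_corpus",
    "read_corpus_jsonl",
    "write_corpus_jsonl",
    "save_corpus",
    "load_corpus",
]

#: Free-text fields of the public study-record schema that make up the
#: "textual content" of a trial.  Configurable everywhere it is consumed.
DEFAULT_FIELD_CONFIG = (
    "brief_title",
    "official_title",
    "brief_summary",
    "detailed_description",
    "condition",
    "intervention_type",
    "intervention_name",
    "keyword",
)

DEFAULT_LABELS = ("nano", "non-nano")

_NCT_RE = re.compile(r"^NCT\d{8}$")


class InvalidRecordError(ValueError):
    """Raised for records without a usable NCT identifier."""


@dataclass(frozen=True)
class CTRecord:
    """One parsed registry entry."""

    nct_id: str
    text: str
    source_fields: tuple[str, ...] = DEFAULT_FIELD_CONFIG

    def __post_init__(self) -> None:
        if not _NCT_RE.match(self.nct_id):
            raise InvalidRecordError(
                f"not a valid NCT identifier: {self.nct_id!r}"
            )


@dataclass
class LabeledCorpus:
    """Ordered records with parallel class labels."""

    records: list[CTRecord]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.records) != len(self.labels):
            raise ValueError("records and labels must have equal length")
        ids = [r.nct_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate nct_id in corpus")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def nct_ids(self) -> list[str]:
        return [r.nct_id for r in self.records]

    @property
    def texts(self) -> list[str]:
        return [r.text for r in self.records]

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for lab in self.labels:
            counts[lab] = counts.get(lab, 0) + 1
        return counts


def parse_ct_record(
    xml_document: str | bytes | Path,
    field_config: Sequence[str] = DEFAULT_FIELD_CONFIG,
) -> CTRecord:
    """Parse one study-record XML document into a :class:`CTRecord`.

    ``xml_document`` may be a path, raw XML string, or bytes.  The record
    text is the character content of the configured fields, joined by
    single newlines in document order; absent fields are skipped silently.

    Raises :class:`lxml.etree.XMLSyntaxError` on malformed XML and
    :class:`InvalidRecordError` when no NCT identifier is found.
    """
    if isinstance(xml_document, Path):
        tree = etree.parse(str(xml_document))
        root = tree.getroot()
    else:
        if isinstance(xml_document, str):
            xml_document = xml_document.encode("utf-8")
        root = etree.fromstring(xml_document)

    nct_el = root.find(".//nct_id")
    if nct_el is None or not (nct_el.text or "").strip():
        raise InvalidRecordError("record has no nct_id element")
    nct_id = nct_el.text.strip()

    wanted = set(field_config)
    chunks: list[str] = []
    for el in root.iter():
        if el.tag in wanted:
            content = " ".join("".join(el.itertext()).split())
            if content:
                chunks.append(content)
    return CTRecord(
        nct_id=nct_id, text="\n".join(chunks), source_fields=tuple(field_config)
    )


def load_label_table(
    table_file: str | Path,
    labels: Sequence[str] = DEFAULT_LABELS,
) -> dict[str, str]:
    """Load a two-column delimited table (header ``nct_id,label``).

    Comma and tab delimiters are auto-detected.  Duplicate ids and labels
    outside the two-value alphabet raise ``ValueError``.
    """
    df = pd.read_csv(table_file, sep=None, engine="python", dtype=str)
    if not {"nct_id", "label"}.issubset(df.columns):
        raise ValueError("label table must have columns nct_id,label")
    dupes = df["nct_id"][df["nct_id"].duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate nct_id in label table: {sorted(set(dupes))}")
    bad = sorted(set(df["label"]) - set(labels))
    if bad:
        raise ValueError(f"unrecognized labels {bad}; expected one of {list(labels)}")
    return dict(zip(df["nct_id"], df["label"]))


def assemble_corpus(
    records: Iterable[CTRecord],
    label_map: Mapping[str, str],
    strict: bool = True,
) -> LabeledCorpus:
    """Join records with their labels into an ordered corpus.

    Ordering is fixed by sorting on nct_id so downstream fold assignment
    is reproducible.  In strict mode an unlabeled record is an error; in
    lenient mode it is dropped.
    """
    kept: list[CTRecord] = []
    labels: list[str] = []
    for rec in sorted(records, key=lambda r: r.nct_id):
        if rec.nct_id not in label_map:
            if strict:
                raise ValueError(f"record {rec.nct_id} has no label")
            continue
        kept.append(rec)
        labels.append(label_map[rec.nct_id])
    return LabeledCorpus(kept, labels)


# ---------------------------------------------------------------------------
# on-disk formats


def write_corpus_jsonl(corpus: LabeledCorpus, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec, lab in zip(corpus.records, corpus.labels):
            fh.write(
                json.dumps(
                    {"nct_id": rec.nct_id, "text": rec.text, "label": lab},
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_corpus_jsonl(path: str | Path) -> LabeledCorpus:
    records, labels = [], []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            records.append(CTRecord(nct_id=obj["nct_id"], text=obj["text"]))
            labels.append(obj["label"])
    return LabeledCorpus(records, labels)


def save_corpus(corpus: LabeledCorpus, directory: str | Path) -> None:
    """Write the on-disk layout: a ``records/`` dir of XML files plus
    ``labels.csv``.

    Each newline-separated segment of the record text is stored as its own
    ``brief_summary`` block, so re-parsing reproduces the newline-joined
    text exactly (original field names are not preserved).  Texts produced
    by :func:`parse_ct_record` always round-trip; arbitrary texts do as
    long as their intra-segment whitespace is already normalized.
    """
    directory = Path(directory)
    rec_dir = directory / "records"
    rec_dir.mkdir(parents=True, exist_ok=True)
    for rec in corpus.records:
        root = etree.Element("clinical_study")
        id_info = etree.SubElement(root, "id_info")
        etree.SubElement(id_info, "nct_id").text = rec.nct_id
        for segment in rec.text.split("\n"):
            summary = etree.SubElement(root, "brief_summary")
            etree.SubElement(summary, "textblock").text = segment
        (rec_dir / f"{rec.nct_id}.xml").write_bytes(
            etree.tostring(root, xml_declaration=True, encoding="utf-8")
        )
    pd.DataFrame(
        {"nct_id": corpus.nct_ids, "label": corpus.labels}
    ).to_csv(directory / "labels.csv", index=False)


def load_corpus(
    directory: str | Path,
    field_config: Sequence[str] = DEFAULT_FIELD_CONFIG,
    labels: Sequence[str] = DEFAULT_LABELS,
    strict: bool = True,
) -> LabeledCorpus:
    """Read the ``records/`` + ``labels.csv`` layout back into a corpus."""
    directory = Path(directory)
    label_map = load_label_table(directory / "labels.csv", labels=labels)
    records = [
        parse_ct_record(p, field_config=field_config)
        for p in sorted((directory / "records").glob("*.xml"))
    ]
    return assemble_corpus(records, label_map, strict=strict)
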