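"""MEDLINE tagged-format I/O and the citation record model.

The "PubMed format" produced by the PubMed *save citations to file* menu is
a plain-text record stream: fields are lines of the form ``TAG - value``
with the tag left-padded to four characters, values continued on lines that
begin with exactly six spaces, and records separated by blank lines.  This
module reads and writes that dialect and holds the two container types the
rest of the package operates on.

Only a handful of tags carry mined semantics (PMID, TI, AB, DP, PT, JT);
everything else is preserved opaquely so a parsed corpus can be written
back out without loss.
"""

from __future__ import annotations

import csv
import io
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, TextIO

logger = logging.getLogger(__name__)

#: Tags with dedicated fields on CitationRecord; all tags, known or not,
#: are also retained in raw_fields for round-tripping.
KNOWN_TAGS = ("PMID", "TI", "AB", "DP", "PT", "JT")

_FIELD_LINE = re.compile(r"^([A-Z][A-Z0-9]{0,3})\s*- (.*)$")
_CONTINUATION = re.compile(r"^ {6}(.*)$")
_YEAR_TOKEN = re.compile(r"\b(\d{4})\b")


@dataclass
class CitationRecord:
    """One parsed citation.

    ``mining_text`` — title and abstract joined by a single space — is the
    text every matcher in the package runs on; records without an abstract
    are mined on the title alone.
    """

    pmid: str
    title: str = ""
    abstract: str = ""
    pub_types: list[str] = field(default_factory=list)
    year: int | None = None
    raw_fields: list[tuple[str, str]] = field(default_factory=list)

    def mining_text(self) -> str:
        return f"{self.title} {self.abstract}".strip()

    def is_review(self) -> bool:
        return any(pt.strip().lower() == "review" for pt in self.pub_types)

    def mined_equal(self, other: "CitationRecord") -> bool:
        """Equality on the mined fields (ignores raw_fields ordering)."""
        return (
            self.pmid == other.pmid
            and self.title == other.title
            and self.abstract == other.abstract
            and self.pub_types == other.pub_types
            and self.year == other.year
        )


@dataclass
class Corpus:
    """A labeled, ordered collection of citation records for one disease."""

    label: str
    records: list[CitationRecord] = field(default_factory=list)
    source_path: str = ""
    snapshot_note: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def _parse_year(dp_value: str) -> int | None:
    """First 4-digit token of the DP (date of publication) field."""
    m = _YEAR_TOKEN.search(dp_value)
    return int(m.group(1)) if m else None


def _finish_record(fields: list[tuple[str, str]]) -> CitationRecord | None:
    pmid = next((v for t, v in fields if t == "PMID"), None)
    if pmid is None or not pmid.strip():
        logger.warning("skipping record block without a PMID field (%d fields)", len(fields))
        return None
    rec = CitationRecord(pmid=pmid.strip(), raw_fields=fields)
    for tag, value in fields:
        if tag == "TI" and not rec.title:
            rec.title = value
        elif tag == "AB" and not rec.abstract:
            rec.abstract = value
        elif tag == "PT":
            rec.pub_types.append(value)
        elif tag == "DP" and rec.year is None:
            rec.year = _parse_year(value)
    return rec


def parse_medline(stream: TextIO | str) -> list[CitationRecord]:
    """Parse a MEDLINE tagged-format stream into citation records.

    Records are blank-line-separated blocks; a block with no PMID is
    skipped with a warning.  A line inside a record that is neither a
    well-formed field line nor a six-space continuation is treated as a
    continuation of the previous field (logged), so a slightly mangled
    export degrades instead of crashing.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)

    records: list[CitationRecord] = []
    fields: list[tuple[str, str]] = []

    def flush() -> None:
        nonlocal fields
        if fields:
            rec = _finish_record(fields)
            if rec is not None:
                records.append(rec)
        fields = []

    for raw_line in stream:
        line = raw_line.rstrip("\r\n")
        if not line.strip():
            flush()
            continue
        m = _FIELD_LINE.match(line)
        if m:
            fields.append((m.group(1), m.group(2)))
            continue
        cont = _CONTINUATION.match(line)
        if cont is not None and fields:
            tag, value = fields[-1]
            joined = f"{value} {cont.group(1)}" if value else cont.group(1)
            fields[-1] = (tag, joined)
            continue
        if fields:
            logger.warning("malformed field line treated as continuation: %r", line[:60])
            tag, value = fields[-1]
            fields[-1] = (tag, f"{value} {line.strip()}")
        else:
            logger.warning("discarding stray line before any field: %r", line[:60])
    flush()
    return records


def read_corpus(path: str, label: str | None = None, snapshot_note: str = "") -> Corpus:
    """Read one MEDLINE file as a corpus; label defaults to the file stem."""
    import os

    with open(path, encoding="utf-8", errors="replace") as fh:
        records = parse_medline(fh)
    if label is None:
        label = os.path.splitext(os.path.basename(path))[0]
    return Corpus(label=label, records=records, source_path=path, snapshot_note=snapshot_note)


def _wrap_value(tag: str, value: str, width: int = 86) -> list[str]:
    """Render one field as a tagged first line plus 6-space continuations."""
    head = f"{tag:<4}- "
    words = value.split(" ")
    lines: list[str] = []
    current = ""
    for word in words:
        candidate = word if not current else f"{current} {word}"
        if current and len(candidate) > width:
            lines.append(current)
            current = word
        else:
            current = candidate
    lines.append(current)
    out = [head + lines[0]]
    out.extend("      " + cont for cont in lines[1:])
    return out


def write_medline(records: Iterable[CitationRecord]) -> str:
    """Serialize records back to MEDLINE tagged text.

    Uses raw_fields when present (full round trip); otherwise emits the
    mined fields.  Long values wrap into six-space continuation lines, and
    since continuations re-join with a single space, parse(write(x))
    preserves every mined field.
    """
    blocks: list[str] = []
    for rec in records:
        fields = rec.raw_fields
        if not fields:
            fields = [("PMID", rec.pmid)]
            if rec.year is not None:
                fields.append(("DP", str(rec.year)))
            if rec.title:
                fields.append(("TI", rec.title))
            if rec.abstract:
                fields.append(("AB", rec.abstract))
            fields.extend(("PT", pt) for pt in rec.pub_types)
        lines: list[str] = []
        for tag, value in fields:
            lines.extend(_wrap_value(tag, value))
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + ("\n" if blocks else "")


def write_corpus(corpus: Corpus, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(write_medline(corpus.records))


def filter_reviews(corpus: Corpus) -> Corpus:
    """Drop every record carrying a "Review" publication type.

    Mirrors the ``NOT (Review[Publication Type])`` clause of the PubMed
    query: a record is excluded if *any* of its publication types equals
    "Review" (case-insensitive).  Order of the survivors is preserved.
    """
    kept = [r for r in corpus.records if not r.is_review()]
    return Corpus(
        label=corpus.label,
        records=kept,
        source_path=corpus.source_path,
        snapshot_note=corpus.snapshot_note,
    )


def corpus_to_table(corpus: Corpus) -> str:
    """Export a corpus as a CSV table (pmid, year, title, abstract, pub_types)."""
    buf = io.StringIO()
    writer = csv.writer(buf)
    writer.writerow(["pmid", "year", "title", "abstract", "pub_types"])
    for rec in corpus.records:
        writer.writerow(
            [rec.pmid, "" if rec.year is None else rec.year, rec.title, rec.abstract,
             "|".join(rec.pub_types)]
        )
    return buf.getvalue()
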