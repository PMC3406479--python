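"""Entry segmentation and stateful occurrence grouping.

A notebook entry is a blank-line-delimited block of text, usually opened by
a date/place header; entries routinely spill across page boundaries, so the
corpus is first concatenated into one document (pages joined by a single
newline, never a blank line) before segmentation.  Occurrence extraction is
a single forward pass over the document's annotations: the walker keeps the
last date and last location annotation seen, and every present taxon
annotation is coupled with that state to form a taxon–date–location
triplet.  Date/location state carries across entries and pages (carried
bindings are flagged so downstream consumers can filter by confidence) but
never across notebooks.
"""

from __future__ import annotations

import bisect
import csv
import re
from dataclasses import dataclass, field

from .annotation import (
    Annotation,
    IssueCode,
    NormalizedDate,
    ParseIssue,
    normalize_date,
    parse_annotations,
)
from .errors import DateParseError
from .ingest import PageCorpus

__all__ = [
    "Entry",
    "OccurrenceTriplet",
    "ExtractionConfig",
    "OffsetMap",
    "concatenate_pages",
    "split_entries",
    "extract_occurrences",
    "extract_from_corpus",
    "write_occurrence_csv",
    "OCCURRENCE_CSV_COLUMNS",
]


class OffsetMap:
    """Bidirectional map between document offsets and (page_number, page offset).

    The document is the in-order page concatenation joined by single
    newlines; the joining newline after page *i* is addressed as
    ``(i, len(page_i))``, keeping the map total and invertible over the
    whole document length.
    """

    def __init__(self, page_lengths: list[int]):
        self.page_lengths = page_lengths
        self.starts = []
        pos = 0
        for length in page_lengths:
            self.starts.append(pos)
            pos += length + 1  # +1 for the joining newline
        self.document_length = max(pos - 1, 0)

    def to_page(self, offset: int) -> tuple[int, int]:
        if not 0 <= offset <= self.document_length:
            raise IndexError(f"document offset {offset} out of range")
        idx = bisect.bisect_right(self.starts, offset) - 1
        return idx + 1, offset - self.starts[idx]

    def to_document(self, page_number: int, page_offset: int) -> int:
        if not 1 <= page_number <= len(self.starts):
            raise IndexError(f"page {page_number} out of range")
        if not 0 <= page_offset <= self.page_lengths[page_number - 1]:
            raise IndexError(
                f"offset {page_offset} out of range for page {page_number}"
            )
        return self.starts[page_number - 1] + page_offset


def concatenate_pages(corpus: PageCorpus) -> tuple[str, OffsetMap]:
    """Join pages into one document so cross-page entries stay contiguous."""
    corpus.validate()
    texts = [p.wikitext for p in corpus.pages]
    return "\n".join(texts), OffsetMap([len(t) for t in texts])


@dataclass
class Entry:
    """One blank-line-delimited notebook entry, possibly spanning pages."""

    notebook_id: str
    entry_index: int          # 1-based, document order
    start_page: int
    end_page: int
    start_offset: int         # document coordinates, half-open
    end_offset: int
    text: str                 # entry text with templates intact
    annotations: list[Annotation] = field(default_factory=list)


_BLANK_RUN_RE = re.compile(r"\n[ \t]*(?:\n[ \t]*)+")


def split_entries(
    document: str,
    offset_map: OffsetMap,
    notebook_id: str = "",
    annotations: list[Annotation] | None = None,
) -> list[Entry]:
    """Segment the document at maximal runs of blank lines.

    Annotations (in document coordinates) are attached to the entry whose
    span contains them.  Leading/trailing blank space belongs to no entry.
    """
    entries: list[Entry] = []
    if not document.strip():
        return entries

    # Non-separator spans between blank-line runs (and document edges).
    spans: list[tuple[int, int]] = []
    pos = 0
    for m in _BLANK_RUN_RE.finditer(document):
        spans.append((pos, m.start()))
        pos = m.end()
    spans.append((pos, len(document)))

    index = 0
    for lo, hi in spans:
        # trim whitespace-only edges so entry text is the visible block
        chunk = document[lo:hi]
        lead = len(chunk) - len(chunk.lstrip())
        trail = len(chunk) - len(chunk.rstrip())
        lo, hi = lo + lead, hi - trail
        if lo >= hi:
            continue
        index += 1
        start_page, _ = offset_map.to_page(lo)
        end_page, _ = offset_map.to_page(hi - 1)
        entries.append(Entry(
            notebook_id=notebook_id, entry_index=index,
            start_page=start_page, end_page=end_page,
            start_offset=lo, end_offset=hi, text=document[lo:hi],
        ))

    if annotations:
        for ann in annotations:
            for entry in entries:
                if entry.start_offset <= ann.char_span[0] < entry.end_offset:
                    entry.annotations.append(ann)
                    break
    return entries


@dataclass
class OccurrenceTriplet:
    """A present (or flagged-absent) taxon coupled with its effective date
    and most recent preceding location."""

    taxon: Annotation
    event_date: NormalizedDate | None
    locality: Annotation | None
    date_carried: bool
    locality_carried: bool
    entry_excerpt: str
    page_number: int
    source_permalink: str
    occurrence_status: str  # "present" | "absent"


@dataclass
class ExtractionConfig:
    """Extraction run options.

    ``absence_list`` holds (page_number, verbatim) pairs to flag as absence
    records, mirroring manual removal of non-presence annotations from
    legacy corpora whose templates predate the status argument.
    ``excerpt_len`` caps the leading entry text copied into each record.
    """

    include_absences: bool = False
    absence_list: set[tuple[int, str]] = field(default_factory=set)
    excerpt_len: int = 200
    year_range: tuple[int, int] | None = None


def extract_occurrences(
    entries: list[Entry],
    config: ExtractionConfig | None = None,
    page_permalinks: dict[int, str] | None = None,
) -> tuple[list[OccurrenceTriplet], list[ParseIssue]]:
    """Single forward pass coupling each taxon with (last date, last location).

    State updates at every date/location annotation in document order; each
    taxon annotation emits one triplet bound to the current state, with
    carried flags set when the bound element originates in an earlier entry.
    Absence-flagged triplets are dropped unless ``include_absences``.
    A taxon seen before any date yields a triplet with a missing date plus
    an ``undated_entry`` warning.
    """
    config = config or ExtractionConfig()
    page_permalinks = page_permalinks or {}
    triplets: list[OccurrenceTriplet] = []
    issues: list[ParseIssue] = []

    last_date: tuple[NormalizedDate, int] | None = None      # (date, entry_index)
    last_location: tuple[Annotation, int] | None = None

    for entry in entries:
        for ann in entry.annotations:
            if ann.kind == "date":
                norm = None
                for slot in (ann.formal, ann.verbatim):
                    try:
                        norm = normalize_date(slot, config.year_range)
                        # verbatimEventDate should carry the notebook's own
                        # wording even when the formal slot was interpreted
                        norm = NormalizedDate(norm.iso, norm.precision,
                                              ann.verbatim)
                        break
                    except DateParseError:
                        continue
                if norm is None:
                    issues.append(ParseIssue(
                        "warning", IssueCode.UNPARSEABLE_DATE, ann.page_number,
                        ann.char_span[0],
                        f"date template {ann.raw!r} has no parseable slot; "
                        "state not updated",
                    ))
                else:
                    last_date = (norm, entry.entry_index)
            elif ann.kind == "location":
                last_location = (ann, entry.entry_index)
            elif ann.kind == "taxon":
                status = ann.status
                if (ann.page_number, ann.verbatim) in config.absence_list:
                    status = "absent"
                if last_date is None:
                    issues.append(ParseIssue(
                        "warning", IssueCode.UNDATED_ENTRY, ann.page_number,
                        ann.char_span[0],
                        f"taxon {ann.formal!r} precedes any date annotation",
                    ))
                triplets.append(OccurrenceTriplet(
                    taxon=ann,
                    event_date=last_date[0] if last_date else None,
                    locality=last_location[0] if last_location else None,
                    date_carried=(last_date is not None
                                  and last_date[1] != entry.entry_index),
                    locality_carried=(last_location is not None
                                      and last_location[1] != entry.entry_index),
                    entry_excerpt=entry.text[: config.excerpt_len],
                    page_number=ann.page_number,
                    source_permalink=page_permalinks.get(ann.page_number, ""),
                    occurrence_status=status,
                ))

    if not config.include_absences:
        triplets = [t for t in triplets if t.occurrence_status == "present"]
    return triplets, issues


def extract_from_corpus(
    corpus: PageCorpus, config: ExtractionConfig | None = None
) -> tuple[list[OccurrenceTriplet], list[Entry], list[ParseIssue]]:
    """Full extraction pipeline for one notebook corpus.

    Parses every page, lifts annotations to document coordinates,
    concatenates, segments into entries, and runs the forward pass.
    Returns (triplets, entries, issues) with parse and extraction issues
    merged in page/offset order.
    """
    document, offset_map = concatenate_pages(corpus)
    all_annotations: list[Annotation] = []
    issues: list[ParseIssue] = []
    for page in corpus.pages:
        anns, page_issues = parse_annotations(page.wikitext, page.page_number)
        issues.extend(page_issues)
        start = offset_map.to_document(page.page_number, 0)
        all_annotations.extend(a.shifted(start) for a in anns)

    entries = split_entries(document, offset_map,
                            corpus.notebook.notebook_id, all_annotations)
    triplets, extraction_issues = extract_occurrences(
        entries, config, corpus.permalinks()
    )
    issues.extend(extraction_issues)
    issues.sort(key=lambda i: (i.page_number, i.char_offset))
    return triplets, entries, issues


OCCURRENCE_CSV_COLUMNS = [
    "taxon_formal", "taxon_verbatim", "event_date", "date_precision",
    "date_carried", "locality_formal", "locality_verbatim", "locality_carried",
    "occurrence_status", "entry_excerpt", "page_number", "source_permalink",
]


def write_occurrence_csv(triplets: list[OccurrenceTriplet], path) -> None:
    """Write the intermediate occurrence table (UTF-8, RFC-4180 quoting)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(OCCURRENCE_CSV_COLUMNS)
        for t in triplets:
            writer.writerow([
                t.taxon.formal,
                t.taxon.verbatim,
                t.event_date.iso if t.event_date else "",
                t.event_date.precision if t.event_date else "",
                str(t.date_carried).lower(),
                t.locality.formal if t.locality else "",
                t.locality.verbatim if t.locality else "",
                str(t.locality_carried).lower(),
                t.occurrence_status,
                t.entry_excerpt,
                t.page_number,
                t.source_permalink,
            ])
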