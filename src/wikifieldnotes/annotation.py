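"""Template grammar: parse wikitext into typed annotations, dates, lint issues.

Notebook transcriptions carry inline annotation templates of the form::

    {{taxon|Sayornis saya|Say Phoebe}}
    {{location|Boulder, Colorado|Boulder, Colo}}
    {{date|1905-07-28|July 28, 1905}}

i.e. ``{{kind|formal interpretation|verbatim text as written}}``.  The
grammar is flat: exactly two positional arguments, pipe-separated, no
nesting.  Taxon templates additionally accept ``status=absent`` to mark a
record of absence.  Parsing is position-faithful — every annotation carries
the half-open character span of its raw template text, so the page can be
reconstructed byte-for-byte from annotations plus inter-annotation text —
and never drops malformed input silently: anything that fails the grammar
becomes a :class:`ParseIssue`.

Hand-entered transcriptions exhibit a small set of recurring error shapes:
missing closing braces, date templates whose interpreted date contradicts
the verbatim text ("Apl 5/07" annotated as April 7), and annotatable terms
left untemplated.  :func:`lint_page` reports all of these.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field
from enum import Enum

from .errors import DateParseError

__all__ = [
    "Annotation",
    "NormalizedDate",
    "ParseIssue",
    "IssueCode",
    "ANNOTATION_KINDS",
    "parse_annotations",
    "normalize_date",
    "lint_page",
]

ANNOTATION_KINDS = ("taxon", "location", "date")


class IssueCode(str, Enum):
    UNBALANCED_BRACES = "unbalanced_braces"
    MISSING_ARGUMENT = "missing_argument"
    UNKNOWN_TEMPLATE = "unknown_template"
    UNDATED_ENTRY = "undated_entry"
    UNPARSEABLE_DATE = "unparseable_date"
    DATE_CONFLICT = "date_conflict"
    POSSIBLE_MISSED_ANNOTATION = "possible_missed_annotation"


@dataclass
class ParseIssue:
    severity: str  # "error" | "warning"
    code: IssueCode
    page_number: int
    char_offset: int
    message: str

    def as_tsv(self) -> str:
        return "\t".join(
            [str(self.page_number), str(self.char_offset), self.severity,
             self.code.value, self.message]
        )


@dataclass
class Annotation:
    """One parsed template instance.

    ``formal`` is the annotator's interpretation (first argument); ``verbatim``
    is the source text exactly as written in the notebook (second argument).
    ``char_span`` is the half-open offset interval of ``raw`` in the page's
    wikitext (or, after corpus concatenation, in the whole document).
    """

    kind: str
    formal: str
    verbatim: str
    page_number: int
    char_span: tuple[int, int]
    raw: str
    status: str = "present"  # "present" | "absent"; absent only for taxa

    def __post_init__(self) -> None:
        if self.kind not in ANNOTATION_KINDS:
            raise ValueError(f"unknown annotation kind {self.kind!r}")
        if self.char_span[0] >= self.char_span[1]:
            raise ValueError("char_span must be non-empty")
        if self.status == "absent" and self.kind != "taxon":
            raise ValueError("status=absent is only legal on taxon annotations")

    def shifted(self, offset: int) -> "Annotation":
        """Copy with char_span translated by ``offset`` (page → corpus coords)."""
        lo, hi = self.char_span
        return Annotation(self.kind, self.formal, self.verbatim, self.page_number,
                          (lo + offset, hi + offset), self.raw, self.status)


@dataclass
class NormalizedDate:
    iso: str            # ISO-8601: YYYY-MM-DD, YYYY-MM or YYYY per precision
    precision: str      # "day" | "month" | "year"
    source_text: str


_TEMPLATE_RE = re.compile(r"\{\{([^{}]*)\}\}")
_BRACE_RE = re.compile(r"\{\{|\}\}")


def _edit_distance_le(a: str, b: str, k: int) -> bool:
    """Banded Levenshtein: is dist(a, b) <= k?  Tiny strings only."""
    if abs(len(a) - len(b)) > k:
        return False
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        if min(cur) > k:
            return False
        prev = cur
    return prev[-1] <= k


def parse_annotations(
    wikitext: str, page_number: int
) -> tuple[list[Annotation], list[ParseIssue]]:
    """Parse one page's markup into annotations (document order) and issues.

    Every well-formed taxon/location/date template yields exactly one
    Annotation.  Non-annotation templates are ignored unless their name is
    within edit distance 1 of one of the three kinds, in which case an
    ``unknown_template`` warning is raised (likely typo).  Stray ``{{`` or
    ``}}`` outside any well-formed template yield ``unbalanced_braces``
    errors.  Nothing is fatal.
    """
    annotations: list[Annotation] = []
    issues: list[ParseIssue] = []
    covered: list[tuple[int, int]] = []

    for m in _TEMPLATE_RE.finditer(wikitext):
        covered.append(m.span())
        parts = m.group(1).split("|")
        name = parts[0].strip().lower()
        positional = [p.strip() for p in parts[1:] if "=" not in p]
        named = dict(
            p.split("=", 1) for p in (q.strip() for q in parts[1:]) if "=" in p
        )
        named = {k.strip().lower(): v.strip().lower() for k, v in named.items()}

        if name not in ANNOTATION_KINDS:
            if name and any(_edit_distance_le(name, k, 1) for k in ANNOTATION_KINDS):
                issues.append(ParseIssue(
                    "warning", IssueCode.UNKNOWN_TEMPLATE, page_number, m.start(),
                    f"template {{{{{name}|…}}}} resembles an annotation kind",
                ))
            continue

        if len(positional) != 2 or not positional[0] or not positional[1]:
            issues.append(ParseIssue(
                "error", IssueCode.MISSING_ARGUMENT, page_number, m.start(),
                f"{name} template needs exactly two non-empty arguments, "
                f"got {len(positional)}",
            ))
            continue

        status = "present"
        if "status" in named:
            if named["status"] == "absent" and name == "taxon":
                status = "absent"
            elif named["status"] not in ("present", "absent") or name != "taxon":
                issues.append(ParseIssue(
                    "warning", IssueCode.UNKNOWN_TEMPLATE, page_number, m.start(),
                    f"unsupported status={named['status']!r} on {name} template",
                ))
        extra = set(named) - {"status"}
        if extra:
            issues.append(ParseIssue(
                "warning", IssueCode.UNKNOWN_TEMPLATE, page_number, m.start(),
                f"unsupported named argument(s) {sorted(extra)} on {name} template",
            ))

        annotations.append(Annotation(
            kind=name, formal=positional[0], verbatim=positional[1],
            page_number=page_number, char_span=m.span(), raw=m.group(0),
            status=status,
        ))

    # Stray braces outside well-formed templates: unbalanced markup.
    for m in _BRACE_RE.finditer(wikitext):
        if not any(lo <= m.start() < hi for lo, hi in covered):
            issues.append(ParseIssue(
                "error", IssueCode.UNBALANCED_BRACES, page_number, m.start(),
                f"stray {m.group(0)!r} outside any well-formed template",
            ))

    issues.sort(key=lambda i: i.char_offset)
    return annotations, issues


# ---------------------------------------------------------------------------
# Date normalization

_MONTHS = {}
for _i, _name in enumerate(
    ["january", "february", "march", "april", "may", "june", "july",
     "august", "september", "october", "november", "december"], start=1
):
    _MONTHS[_name] = _i
    _MONTHS[_name[:3]] = _i
_MONTHS["sept"] = 9
_MONTHS["apl"] = 4   # Henderson-era abbreviation for April

_WEEKDAY_RE = re.compile(
    r"^(?:mon|tues?|wed(?:nes)?|thu(?:rs)?|fri|sat(?:ur)?|sun)(?:day)?\.?,?\s+",
    re.IGNORECASE,
)
_ISO_RE = re.compile(r"^(\d{4})(?:-(\d{1,2})(?:-(\d{1,2}))?)?$")
_MDY_RE = re.compile(r"^([A-Za-z]+)\.?\s+(\d{1,2})(?:st|nd|rd|th)?,?\s+(\d{4})$")
_SLASH_RE = re.compile(r"^([A-Za-z]+)\.?\s+(\d{1,2})\s*/\s*(\d{2})$")
_MY_RE = re.compile(r"^([A-Za-z]+)\.?,?\s+(\d{4})$")


def _month_number(token: str) -> int | None:
    return _MONTHS.get(token.lower().rstrip("."))


def _resolve_century(yy: int, year_range: tuple[int, int] | None) -> int:
    """Resolve a two-digit year against the notebook's configured date range."""
    if year_range is not None:
        lo, hi = year_range
        for century in range(lo - lo % 100, hi + 100, 100):
            candidate = century + yy
            if lo <= candidate <= hi:
                return candidate
    return 1900 + yy  # field-notebook era default when no range is configured


def normalize_date(
    text: str, year_range: tuple[int, int] | None = None
) -> NormalizedDate:
    """Normalize a notebook date string to an ISO calendar date.

    Handles ISO dates, full month-name dates ("July 28, 1905"), weekday
    prefixes ("Sunday, June 10, 1906"), abbreviated-month slash-year forms
    ("Apl 5/07", century resolved inside ``year_range``), and month- or
    year-only forms (returned at precision "month"/"year").

    Raises :class:`DateParseError` on anything else.
    """
    if not text or not text.strip():
        raise DateParseError(text, "empty date string")
    stripped = _WEEKDAY_RE.sub("", text.strip())

    m = _ISO_RE.match(stripped)
    if m:
        year, month, day = m.group(1), m.group(2), m.group(3)
        return _build(text, int(year), int(month) if month else None,
                      int(day) if day else None)

    m = _MDY_RE.match(stripped)
    if m:
        month = _month_number(m.group(1))
        if month is not None:
            return _build(text, int(m.group(3)), month, int(m.group(2)))

    m = _SLASH_RE.match(stripped)
    if m:
        month = _month_number(m.group(1))
        if month is not None:
            year = _resolve_century(int(m.group(3)), year_range)
            return _build(text, year, month, int(m.group(2)))

    m = _MY_RE.match(stripped)
    if m:
        month = _month_number(m.group(1))
        if month is not None:
            return _build(text, int(m.group(2)), month, None)

    raise DateParseError(text)


def _build(source: str, year: int, month: int | None, day: int | None) -> NormalizedDate:
    if month is None:
        return NormalizedDate(f"{year:04d}", "year", source)
    if day is None:
        if not 1 <= month <= 12:
            raise DateParseError(source, f"month {month} out of range")
        return NormalizedDate(f"{year:04d}-{month:02d}", "month", source)
    try:
        _dt.date(year, month, day)
    except ValueError as exc:
        raise DateParseError(source, str(exc)) from exc
    return NormalizedDate(f"{year:04d}-{month:02d}-{day:02d}", "day", source)


# ---------------------------------------------------------------------------
# Linting

_CAPITALIZED_RE = re.compile(r"\b[A-Z][a-z]{3,}s?\b")


def lint_page(
    wikitext: str,
    page_number: int,
    year_range: tuple[int, int] | None = None,
    known_vocabulary: set[str] | None = None,
) -> list[ParseIssue]:
    """Report parse issues plus proofreading heuristics for one page.

    Beyond grammar errors, flags (a) date templates whose formal date
    disagrees with the normalized verbatim text — the classic
    mis-annotation shape where "Apl 5/07" is interpreted as April 7 — and
    (b) capitalized terms matching known taxon/place vocabulary that occur
    outside any template (possible missed annotations).  Heuristics are
    warnings only.
    """
    annotations, issues = parse_annotations(wikitext, page_number)

    vocab = {v.lower() for v in (known_vocabulary or set())}
    for ann in annotations:
        if ann.kind == "date":
            formal = verbatim = None
            try:
                formal = normalize_date(ann.formal, year_range)
            except DateParseError:
                pass
            try:
                verbatim = normalize_date(ann.verbatim, year_range)
            except DateParseError:
                pass
            if formal is None and verbatim is None:
                issues.append(ParseIssue(
                    "warning", IssueCode.UNPARSEABLE_DATE, page_number,
                    ann.char_span[0],
                    f"date template {ann.raw!r}: neither slot parses as a date",
                ))
            elif formal and verbatim and formal.iso != verbatim.iso:
                issues.append(ParseIssue(
                    "warning", IssueCode.DATE_CONFLICT, page_number,
                    ann.char_span[0],
                    f"formal date {formal.iso} conflicts with verbatim "
                    f"{ann.verbatim!r} ({verbatim.iso})",
                ))
        # Page-local vocabulary: verbatim terms already annotated here,
        # both whole phrases and their content words.
        vocab.add(ann.verbatim.lower())
        for word in re.findall(r"[A-Za-z]{4,}", ann.verbatim):
            vocab.add(word.lower())
            vocab.add(word.lower().rstrip("s"))

    spans = [a.char_span for a in annotations]
    for m in _CAPITALIZED_RE.finditer(wikitext):
        if any(lo <= m.start() < hi for lo, hi in spans):
            continue
        word = m.group(0).lower()
        if word in vocab or word.rstrip("s") in vocab:
            issues.append(ParseIssue(
                "warning", IssueCode.POSSIBLE_MISSED_ANNOTATION, page_number,
                m.start(),
                f"{m.group(0)!r} matches annotated vocabulary but is not "
                "inside any template",
            ))

    issues.sort(key=lambda i: i.char_offset)
    return issues
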