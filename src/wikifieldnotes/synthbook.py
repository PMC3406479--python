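"""Synthetic wiki-markup notebooks with known ground truth.

Real annotated notebooks live on a wiki and cannot ship with a test suite,
so every pipeline stage is exercised against generated corpora that
emulate the structure of an early-1900s naturalist's notebook: multi-page
runs of blank-line-separated entries, each usually opened by a place/date
header and containing zero to dozens of inline taxon templates; entries
that spill across page boundaries with no blank line at the break;
occasional malformed templates; occasional absence records.

The generator is deterministic under its seed and emits, alongside the
corpus, a :class:`GroundTruth` enumerating every expected downstream
output: entry count, per-kind annotation counts, the exact
taxon–date–location triplets with carried flags, the injected malformed
template count, and the expected name-resolution class of every query
(names are drawn from the bundled authority snapshots so referencing
outcomes are controllable).

:func:`make_henderson_fixture` hand-writes a three-page corpus encoding
the two canonical worked examples: a first-sentence entry with one
location, one date and four taxa, and a cross-page entry whose location
and date sit on one page while its taxon sits on the next.
"""

from __future__ import annotations

import datetime as _dt
import random
from dataclasses import dataclass, field

from .errors import ConfigurationError
from .ingest import NotebookRef, PageCorpus, RawPage
from .referencing import Authority, bundled_authority_path, load_authority, normalize_name

__all__ = [
    "SynthConfig",
    "TripletTruth",
    "GroundTruth",
    "generate_notebook",
    "make_henderson_fixture",
    "default_authorities",
    "CLASS_CONSISTENT",
    "CLASS_A",
    "CLASS_B",
    "CLASS_UNRESOLVED",
]

CLASS_CONSISTENT = "consistent"
CLASS_A = "authority_a_preferred"
CLASS_B = "authority_b_preferred"
CLASS_UNRESOLVED = "unresolved"
_CLASSES = (CLASS_CONSISTENT, CLASS_A, CLASS_B, CLASS_UNRESOLVED)

# Entry shape defaults approximate the annotated Henderson notebooks:
# ~0.6 entries per page, ~5 taxa per entry with a long tail (observed
# range 0..33), most entries opened by a dated place header.
_DEFAULT_TAXA_WEIGHTS = {
    0: 0.08, 1: 0.14, 2: 0.18, 3: 0.18, 4: 0.14, 5: 0.10, 6: 0.07,
    8: 0.05, 10: 0.03, 15: 0.015, 22: 0.01, 33: 0.005,
}
# Paper-scale resolution-class mix: 560/195/83/238 of 1,076 queries.
_DEFAULT_COMPOSITION = {
    CLASS_CONSISTENT: 560 / 1076,
    CLASS_A: 195 / 1076,
    CLASS_B: 83 / 1076,
    CLASS_UNRESOLVED: 238 / 1076,
}

_PLACES = [
    ("Boulder, Colorado", "Boulder, Colo"),
    ("Big Thompson Creek near Loveland", "Big Thompson Creek near Loveland"),
    ("Ward, Colorado", "Ward"),
    ("Nederland, Colorado", "Nederland"),
    ("Gold Hill, Colorado", "Gold Hill"),
    ("Left Hand Canyon, Colorado", "Left Hand Canon"),
    ("Eldora, Colorado", "Eldora"),
    ("Sunshine Canyon, Colorado", "Sunshine Canon"),
    ("Gregory Canyon, Colorado", "Gregory Canon"),
    ("Valmont Butte, Colorado", "Valmont"),
    ("St. Vrain Creek, Colorado", "St. Vrain"),
    ("Flagstaff Mountain, Colorado", "Flagstaff Mtn"),
]

_FILLERS = [
    "Walked up the canon in the morning.",
    "Cold wind from the northwest all day.",
    "Collected a few shells along the ditch.",
    "Train late again; waited at the depot.",
    "Snow still deep on the north slopes.",
    "Clear and warm; meadows full of bloom.",
]

_MONTH_NAMES = ["January", "February", "March", "April", "May", "June", "July",
                "August", "September", "October", "November", "December"]
_WEEKDAY_NAMES = ["Monday", "Tuesday", "Wednesday", "Thursday", "Friday",
                  "Saturday", "Sunday"]
_MONTH_ABBR = {4: "Apl", 9: "Sept"}  # era spellings; others use 3 letters


@dataclass
class SynthConfig:
    """Study conditions for one synthetic notebook.

    Counts given exactly (``n_entries``, ``n_taxa``, ...) are honored
    exactly; otherwise sizes are drawn from the configured distributions.
    ``authority_composition`` sets the fraction of taxon queries expected
    to resolve consistently / by one authority only / not at all;
    ``class_counts`` pins those counts exactly instead.
    """

    seed: int = 0
    notebook_id: str = "synthetic-1"
    n_pages: int = 8
    n_entries: int | None = None
    entries_per_page: tuple[int, int] = (0, 2)
    taxa_per_entry_weights: dict[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_TAXA_WEIGHTS))
    n_taxa: int | None = None
    n_locations: int | None = None
    n_dates: int | None = None
    cross_page_split_prob: float = 0.2
    malformed_template_rate: float = 0.0
    absence_rate: float = 0.0
    n_absent: int | None = None
    n_invalid: int | None = None
    date_gap_prob: float = 0.15
    location_gap_prob: float = 0.10
    year_range: tuple[int, int] = (1905, 1907)
    authority_composition: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_COMPOSITION))
    class_counts: dict[str, int] | None = None

    def validate(self) -> None:
        probs = [self.cross_page_split_prob, self.malformed_template_rate,
                 self.absence_rate, self.date_gap_prob, self.location_gap_prob]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigurationError("probabilities must lie in [0, 1]")
        if self.n_pages < 1:
            raise ConfigurationError("n_pages must be >= 1")
        if self.cross_page_split_prob > 0 and self.n_pages < 2:
            raise ConfigurationError(
                "cross-page splits are infeasible with a single page")
        if abs(sum(self.authority_composition.values()) - 1.0) > 1e-9:
            raise ConfigurationError("authority_composition must sum to 1")
        if not self.taxa_per_entry_weights:
            raise ConfigurationError("taxa_per_entry_weights must be non-empty")


@dataclass
class TripletTruth:
    """One expected occurrence triplet, in document order."""

    taxon_formal: str
    taxon_verbatim: str
    event_date: str | None       # ISO
    locality_verbatim: str | None
    date_carried: bool
    locality_carried: bool
    page_number: int
    status: str                  # "present" | "absent" (absent covers invalids)
    template_absent: bool        # marked absent in the template itself
    invalid: bool                # destined for the manual exclusion list
    resolution_class: str | None  # None for template-absent records

    def key(self) -> tuple:
        return (self.taxon_formal, self.taxon_verbatim, self.event_date,
                self.locality_verbatim, self.date_carried,
                self.locality_carried, self.page_number, self.status)


@dataclass
class GroundTruth:
    seed: int
    n_entries: int
    n_annotations: dict[str, int]
    n_malformed: int
    triplets: list[TripletTruth]
    exclusion_list: set[tuple[int, str]]
    resolution_class_counts: dict[str, int]

    def validate(self) -> None:
        present = sum(1 for t in self.triplets if t.status == "present")
        absent = sum(1 for t in self.triplets if t.status == "absent")
        if present + absent != self.n_annotations.get("taxon", 0):
            raise ConfigurationError("ground truth internally inconsistent")


def default_authorities() -> tuple[Authority, Authority]:
    """The bundled synthetic EOL-like and ITIS-like snapshots."""
    return (
        load_authority(bundled_authority_path("eol"), "EOL"),
        load_authority(bundled_authority_path("itis"), "ITIS"),
    )


def _name_pools(
    auth_a: Authority, auth_b: Authority
) -> dict[str, list[tuple[str, str]]]:
    """Derive per-class (formal, vernacular) name pools from the snapshots.

    consistent: same accepted name and kingdom in both authorities;
    A/B-only: present in exactly one.  Cross-kingdom homonyms fall into
    neither pool.  The unresolved pool is synthesized at draw time.
    """
    def entries(auth: Authority) -> dict[str, tuple[str, str, str]]:
        out = {}
        for rec in auth.records:
            norm = normalize_name(rec.name)
            vern = rec.vernaculars[0] if rec.vernaculars else rec.name
            out.setdefault(norm, (rec.name, vern,
                                  rec.higher_taxonomy.get("kingdom", "")))
        return out

    in_a, in_b = entries(auth_a), entries(auth_b)
    pools: dict[str, list[tuple[str, str]]] = {
        CLASS_CONSISTENT: [], CLASS_A: [], CLASS_B: []}
    for norm, (name, vern, kingdom) in sorted(in_a.items()):
        if norm in in_b:
            if in_b[norm][2] == kingdom:
                pools[CLASS_CONSISTENT].append((name, vern))
        else:
            pools[CLASS_A].append((name, vern))
    for norm, (name, vern, _) in sorted(in_b.items()):
        if norm not in in_a:
            pools[CLASS_B].append((name, vern))
    return pools


def _largest_remainder(fractions: dict[str, float], total: int) -> dict[str, int]:
    raw = {k: f * total for k, f in fractions.items()}
    counts = {k: int(v) for k, v in raw.items()}
    leftover = total - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:leftover]:
        counts[k] += 1
    return counts


def _format_date(day: _dt.date, style: int) -> str:
    """Render a calendar date in one of Henderson's written forms."""
    month = _MONTH_NAMES[day.month - 1]
    if style == 0:
        return f"{month} {day.day}, {day.year}"
    if style == 1:
        weekday = _WEEKDAY_NAMES[day.weekday()]
        return f"{weekday}, {month} {day.day}, {day.year}"
    abbr = _MONTH_ABBR.get(day.month, month[:3])
    return f"{abbr} {day.day}/{day.year % 100:02d}"


class _Token:
    """One rendered piece of an entry: plain text or an annotation."""

    __slots__ = ("text", "kind", "formal", "verbatim", "status", "meta")

    def __init__(self, text, kind=None, formal=None, verbatim=None,
                 status="present", meta=None):
        self.text = text
        self.kind = kind
        self.formal = formal
        self.verbatim = verbatim
        self.status = status
        self.meta = meta or {}


def _template(kind: str, formal: str, verbatim: str, status: str = "present") -> str:
    if status == "absent":
        return f"{{{{{kind}|{formal}|{verbatim}|status=absent}}}}"
    return f"{{{{{kind}|{formal}|{verbatim}}}}}"


def generate_notebook(
    config: SynthConfig,
    authorities: tuple[Authority, Authority] | None = None,
) -> tuple[PageCorpus, GroundTruth]:
    """Generate one synthetic notebook corpus plus its ground truth.

    Deterministic under ``config.seed``; the emitted wikitext uses exactly
    the annotation template grammar, so a clean configuration (no injected
    malformations) round-trips through the pipeline to ground truth
    exactly.
    """
    config.validate()
    rng = random.Random(config.seed)
    auth_a, auth_b = authorities or default_authorities()
    pools = _name_pools(auth_a, auth_b)

    # ----- sizes -------------------------------------------------------
    if config.n_entries is not None:
        n_entries = config.n_entries
    else:
        lo, hi = config.entries_per_page
        n_entries = sum(rng.randint(lo, hi) for _ in range(config.n_pages))
        n_entries = max(n_entries, 1)

    values = sorted(config.taxa_per_entry_weights)
    weights = [config.taxa_per_entry_weights[v] for v in values]
    taxa_per_entry = [rng.choices(values, weights)[0] for _ in range(n_entries)]
    if config.n_taxa is not None:
        delta = config.n_taxa - sum(taxa_per_entry)
        while delta != 0:
            i = rng.randrange(n_entries)
            if delta > 0:
                taxa_per_entry[i] += 1
                delta -= 1
            elif taxa_per_entry[i] > 0:
                taxa_per_entry[i] -= 1
                delta += 1
    n_taxa = sum(taxa_per_entry)

    # Which entries carry their own date / location header (entry 1 always
    # does, so the notebook never opens with an unbound taxon).
    def _allocate(n_exact: int | None, gap_prob: float) -> list[int]:
        """Per-entry annotation counts for one header kind (>= n_entries
        allowed: extra locations mid-entry are realistic)."""
        if n_exact is None:
            counts = [1 if (i == 0 or rng.random() >= gap_prob) else 0
                      for i in range(n_entries)]
            return counts
        counts = [0] * n_entries
        counts[0] = 1
        remaining = n_exact - 1
        if remaining < 0:
            raise ConfigurationError("need at least one header annotation")
        # first pass: one per entry while supply lasts, random order
        order = list(range(1, n_entries))
        rng.shuffle(order)
        for i in order:
            if remaining == 0:
                break
            counts[i] += 1
            remaining -= 1
        while remaining > 0:  # surplus: extra annotations in random entries
            counts[rng.randrange(n_entries)] += 1
            remaining -= 1
        return counts

    dates_per_entry = _allocate(config.n_dates, config.date_gap_prob)
    locs_per_entry = _allocate(config.n_locations, config.location_gap_prob)
    n_dates = sum(dates_per_entry)
    n_locations = sum(locs_per_entry)

    # ----- absence / invalid / resolution-class assignment -------------
    taxon_slots = list(range(n_taxa))
    n_absent = (config.n_absent if config.n_absent is not None
                else sum(rng.random() < config.absence_rate for _ in taxon_slots))
    n_absent = min(n_absent, n_taxa)
    absent_set = set(rng.sample(taxon_slots, n_absent))
    nonabsent = [s for s in taxon_slots if s not in absent_set]
    n_invalid = min(config.n_invalid or 0, len(nonabsent))
    invalid_set = set(rng.sample(nonabsent, n_invalid))

    if config.class_counts is not None:
        class_counts = dict(config.class_counts)
        if sum(class_counts.values()) != len(nonabsent):
            raise ConfigurationError(
                f"class_counts sum {sum(class_counts.values())} != "
                f"non-absent taxa {len(nonabsent)}")
    else:
        class_counts = _largest_remainder(config.authority_composition,
                                          len(nonabsent))
    class_sequence: list[str] = []
    for cls in _CLASSES:
        class_sequence.extend([cls] * class_counts.get(cls, 0))
    rng.shuffle(class_sequence)
    slot_class = dict(zip(nonabsent, class_sequence))
    # absent slots draw names from the consistent pool; class not counted
    for s in absent_set:
        slot_class[s] = CLASS_CONSISTENT

    # ----- build entry token streams -----------------------------------
    lo_year, hi_year = config.year_range
    current = _dt.date(lo_year, 1 + rng.randrange(3), 1 + rng.randrange(27))
    last_day = _dt.date(hi_year, 12, 28)

    invented = 0
    invalid_counter = 0
    slot = 0
    entries_tokens: list[list[_Token]] = []
    truth_stream: list[dict] = []  # per-token truth info in document order

    for e in range(n_entries):
        tokens: list[_Token] = []
        header: list[str] = []
        for _ in range(locs_per_entry[e]):
            formal, verbatim = _PLACES[rng.randrange(len(_PLACES))]
            tokens.append(_Token(_template("location", formal, verbatim),
                                 kind="location", formal=formal, verbatim=verbatim))
            tokens.append(_Token(". "))
        for _ in range(dates_per_entry[e]):
            step = rng.randint(0, 5)
            if current + _dt.timedelta(days=step) <= last_day:
                current = current + _dt.timedelta(days=step)
            verbatim = _format_date(current, rng.randrange(3))
            iso = current.isoformat()
            tokens.append(_Token(_template("date", iso, verbatim),
                                 kind="date", formal=iso, verbatim=verbatim,
                                 meta={"iso": iso}))
            tokens.append(_Token(". "))

        for _ in range(taxa_per_entry[e]):
            cls = slot_class[slot]
            if cls == CLASS_UNRESOLVED:
                invented += 1
                formal = f"Fictusaurus inventus{invented}"
                verbatim = f"the creature no. {invented}"
            else:
                formal, vern = pools[cls][rng.randrange(len(pools[cls]))]
                verbatim = vern.lower() + ("s" if rng.random() < 0.4 and
                                           not vern.lower().endswith("s") else "")
            status = "present"
            invalid = slot in invalid_set
            if invalid:
                invalid_counter += 1
                verbatim = f"{verbatim} (doubtful no. {invalid_counter})"
            if slot in absent_set:
                status = "absent"
                tokens.append(_Token("Noted the entire absence of "))
                tokens.append(_Token(
                    _template("taxon", formal, verbatim, "absent"),
                    kind="taxon", formal=formal, verbatim=verbatim,
                    status="absent",
                    meta={"class": None, "invalid": False}))
                tokens.append(_Token(" on this trip. "))
            else:
                tokens.append(_Token("Saw "))
                tokens.append(_Token(
                    _template("taxon", formal, verbatim),
                    kind="taxon", formal=formal, verbatim=verbatim,
                    meta={"class": cls, "invalid": invalid}))
                tokens.append(_Token(" along the way. "))
            slot += 1

        tokens.append(_Token(_FILLERS[rng.randrange(len(_FILLERS))]))
        if rng.random() < config.malformed_template_rate:
            bad = rng.choice(["{{taxon|Lostbird", "{{location|Somewhere",
                              "{{date|1906-01-01"])
            tokens.append(_Token(" " + bad + " trailing note without close."))
            tokens[-1].meta["malformed"] = True
        entries_tokens.append(tokens)

    n_malformed = sum(1 for toks in entries_tokens for t in toks
                      if t.meta.get("malformed"))

    # ----- paginate -----------------------------------------------------
    per_page = _largest_remainder(
        {str(i): 1 / config.n_pages for i in range(config.n_pages)}, n_entries)
    entries_on_page = [per_page[str(i)] for i in range(config.n_pages)]

    page_texts = [""] * config.n_pages
    continues = [False] * config.n_pages  # page i's last entry spills to i+1
    entry_iter = iter(range(n_entries))
    assignments: list[list[tuple[int, int | None]]] = [[] for _ in range(config.n_pages)]
    # assignments[p] = list of (entry_index, split_token_boundary or None)
    for p in range(config.n_pages):
        for _ in range(entries_on_page[p]):
            assignments[p].append((next(entry_iter), None))

    # choose splits: move the tail of the last entry of page p to page p+1
    for p in range(config.n_pages - 1):
        if not assignments[p]:
            continue
        e_idx, _ = assignments[p][-1]
        toks = entries_tokens[e_idx]
        if len(toks) >= 2 and rng.random() < config.cross_page_split_prob:
            boundary = rng.randint(1, len(toks) - 1)
            assignments[p][-1] = (e_idx, boundary)

    # render pages, recording each annotation's page number
    annotation_pages: dict[int, int] = {}  # id(token) -> page_number
    for p in range(config.n_pages):
        parts: list[str] = []
        # tail of a split entry from the previous page starts this page
        if p > 0 and continues[p - 1]:
            e_idx, boundary = assignments[p - 1][-1]
            tail = entries_tokens[e_idx][boundary:]
            parts.append(_render(tail, p + 1, annotation_pages))
        for e_idx, boundary in assignments[p]:
            toks = entries_tokens[e_idx]
            if boundary is not None and p + 1 < config.n_pages:
                continues[p] = True
                parts.append(_render(toks[:boundary], p + 1, annotation_pages))
            else:
                parts.append(_render(toks, p + 1, annotation_pages))
        page_texts[p] = "\n\n".join(x for x in parts if x)

    # a page whose last entry is complete ends with a newline, so the
    # single-newline page join yields a blank line between distinct entries
    for p in range(config.n_pages - 1):
        if page_texts[p] and not continues[p]:
            page_texts[p] += "\n"

    # ----- ground truth triplets ---------------------------------------
    triplets: list[TripletTruth] = []
    exclusion: set[tuple[int, str]] = set()
    last_date: tuple[str, int] | None = None
    last_loc: tuple[str, int] | None = None
    class_totals = {c: 0 for c in _CLASSES}
    counts = {"taxon": 0, "location": 0, "date": 0}
    for e_idx, toks in enumerate(entries_tokens, start=1):
        for tok in toks:
            if tok.kind is None:
                continue
            counts[tok.kind] += 1
            if tok.kind == "date":
                last_date = (tok.meta["iso"], e_idx)
            elif tok.kind == "location":
                last_loc = (tok.verbatim, e_idx)
            else:
                page = annotation_pages[id(tok)]
                invalid = tok.meta.get("invalid", False)
                template_absent = tok.status == "absent"
                if invalid:
                    exclusion.add((page, tok.verbatim))
                status = "absent" if (template_absent or invalid) else "present"
                cls = tok.meta.get("class")
                if cls is not None:
                    class_totals[cls] += 1
                triplets.append(TripletTruth(
                    taxon_formal=tok.formal,
                    taxon_verbatim=tok.verbatim,
                    event_date=last_date[0] if last_date else None,
                    locality_verbatim=last_loc[0] if last_loc else None,
                    date_carried=bool(last_date and last_date[1] != e_idx),
                    locality_carried=bool(last_loc and last_loc[1] != e_idx),
                    page_number=page,
                    status=status,
                    template_absent=template_absent,
                    invalid=invalid,
                    resolution_class=cls,
                ))

    truth = GroundTruth(
        seed=config.seed,
        n_entries=n_entries,
        n_annotations=counts,
        n_malformed=n_malformed,
        triplets=triplets,
        exclusion_list=exclusion,
        resolution_class_counts=class_totals,
    )
    truth.validate()

    notebook = NotebookRef(
        notebook_id=config.notebook_id,
        index_title=f"Index:{config.notebook_id}",
        page_titles=[f"Page:{config.notebook_id}/{i + 1}"
                     for i in range(config.n_pages)],
    )
    pages = []
    for i, text in enumerate(page_texts, start=1):
        rev = f"{config.seed}{i:04d}"
        pages.append(RawPage(
            page_number=i,
            title=f"Page:{config.notebook_id}/{i}",
            revision_id=rev,
            timestamp="1970-01-01T00:00:00+00:00",
            permalink=(f"https://example.org/w/index.php?title="
                       f"Page:{config.notebook_id}/{i}&oldid={rev}"),
            wikitext=text,
        ))
    corpus = PageCorpus(notebook, pages)
    corpus.validate()
    return corpus, truth


def _render(tokens: list[_Token], page_number: int,
            annotation_pages: dict[int, int]) -> str:
    for tok in tokens:
        if tok.kind is not None:
            annotation_pages[id(tok)] = page_number
    return "".join(t.text for t in tokens).strip()


def henderson_scale_configs(seed: int = 0) -> list[SynthConfig]:
    """Three notebook configurations at annotated-corpus scale.

    Sizes mirror the annotated Henderson pilot corpus: 352 pages and 222
    entries across three notebooks; per-notebook annotation totals 632,
    703 and 1007 (taxa 349/224/514, places 219/419/401, dates 64/60/92);
    eleven absence records and eight annotations destined for manual
    removal; name-resolution classes totalling 560 consistent, 195
    EOL-preferred, 83 ITIS-preferred and 238 unresolved over the 1,076
    non-absence queries.  Entry splits per notebook (66/60/96) follow the
    notebooks' date-header counts.  Seeded deterministically from ``seed``.
    """
    specs = [
        ("notebook-1", 118, 66, 349, 219, 64, 4, 3, (180, 63, 27, 75),
         (1905, 1907)),
        ("notebook-2", 117, 60, 224, 419, 60, 3, 2, (110, 40, 17, 54),
         (1907, 1908)),
        ("notebook-3", 117, 96, 514, 401, 92, 4, 3, (270, 92, 39, 109),
         (1909, 1909)),
    ]
    configs = []
    for i, (nb, pages, entries, taxa, locs, dates, absent, invalid,
            (c, a, b, u), years) in enumerate(specs):
        configs.append(SynthConfig(
            seed=(seed * 16 + i) % (2 ** 31),
            notebook_id=nb,
            n_pages=pages, n_entries=entries, n_taxa=taxa,
            n_locations=locs, n_dates=dates,
            n_absent=absent, n_invalid=invalid,
            year_range=years,
            class_counts={CLASS_CONSISTENT: c, CLASS_A: a,
                          CLASS_B: b, CLASS_UNRESOLVED: u},
        ))
    return configs


# ---------------------------------------------------------------------------
# Hand-written worked-example fixture

_P1 = ("{{location|Boulder, Colorado|Boulder, Colo}}. "
       "{{date|1905-07-28|July 28, 1905}}. "
       "Saw {{taxon|Sayornis saya|Say [sic] Phoebe}} and "
       "{{taxon|Carduelis pinus|siskins}}, "
       "{{taxon|Turdus migratorius|[American] Robins}}, "
       "{{taxon|Colaptes auratus|[Northern] Flicker}}.\n")

_P2 = ("{{location|Big Thompson Creek near Loveland|Big Thompson Creek near "
       "Loveland}}. {{date|1906-06-10|Sunday, June 10, 1906}}. "
       "Rode down the creek in the morning and camped in a grove")

_P3 = "of large {{taxon|Populus|Cottonwood}} trees near the water."


def make_henderson_fixture() -> tuple[PageCorpus, GroundTruth]:
    """Three-page corpus encoding the two canonical worked examples.

    Page 1 holds a complete first-sentence entry (1 location, 1 date, 4
    taxa).  A second entry opens on page 2 with a location and date and
    runs onto page 3, where its single taxon sits — the cross-page
    grouping case.  Pipeline output: five occurrence records.
    """
    notebook = NotebookRef("henderson-demo", "Index:henderson-demo")
    pages = []
    for i, text in enumerate([_P1, _P2, _P3], start=1):
        rev = f"demo{i:03d}"
        pages.append(RawPage(
            page_number=i, title=f"Page:henderson-demo/{i}",
            revision_id=rev, timestamp="2012-03-27T00:00:00+00:00",
            permalink=(f"https://example.org/w/index.php?title="
                       f"Page:henderson-demo/{i}&oldid={rev}"),
            wikitext=text,
        ))
    notebook.page_titles = [p.title for p in pages]
    corpus = PageCorpus(notebook, pages)

    def t(formal, verbatim, date, loc, page, carried=(False, False)):
        return TripletTruth(formal, verbatim, date, loc, carried[0], carried[1],
                            page, "present", False, False, CLASS_CONSISTENT)

    truth = GroundTruth(
        seed=0,
        n_entries=2,
        n_annotations={"taxon": 5, "location": 2, "date": 2},
        n_malformed=0,
        triplets=[
            t("Sayornis saya", "Say [sic] Phoebe", "1905-07-28", "Boulder, Colo", 1),
            t("Carduelis pinus", "siskins", "1905-07-28", "Boulder, Colo", 1),
            t("Turdus migratorius", "[American] Robins", "1905-07-28",
              "Boulder, Colo", 1),
            t("Colaptes auratus", "[Northern] Flicker", "1905-07-28",
              "Boulder, Colo", 1),
            t("Populus", "Cottonwood", "1906-06-10",
              "Big Thompson Creek near Loveland", 3),
        ],
        exclusion_list=set(),
        resolution_class_counts={CLASS_CONSISTENT: 5, CLASS_A: 0, CLASS_B: 0,
                                 CLASS_UNRESOLVED: 0},
    )
    truth.validate()
    return corpus, truth
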