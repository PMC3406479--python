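# Methods

## The extraction model

An occurrence record needs three elements: a taxon, a place, and a time.
In an annotated notebook transcription these arrive as inline templates
(`{{taxon|…}}`, `{{location|…}}`, `{{date|…}}`) scattered through entry
prose, with place/date headers usually opening an entry and taxa following
in any number (zero to dozens). The pipeline's core procedure is:

1. **Concatenate pages** into one document, joining pages with a single
   newline. Entries are delimited by blank lines, and a page break is not
   an entry break, so an entry whose header sits at the bottom of one page
   and whose taxa sit at the top of the next stays contiguous. A total,
   invertible offset map preserves the document-offset ↔ (page, offset)
   correspondence; the joining newline after page *i* is addressed as
   `(i, len(page_i))`.
2. **Segment** at maximal runs of blank lines (a blank line is a line
   containing only whitespace; runs collapse to one boundary). Entry page
   spans are derived through the offset map.
3. **Forward pass.** Walk annotations in document order keeping one state
   pair: the last date and the last location encountered. Every taxon
   annotation emits one triplet bound to the current state. State carries
   across entries and pages but resets across notebooks; when a bound
   element originates in an earlier entry than its taxon, the triplet's
   `date_carried` / `locality_carried` flag is set so downstream users can
   filter by binding confidence. If an entry contains several dates, taxa
   after the second date bind to it — the single-state model reads the
   entry as a chronological narrative. A location appearing *after* a
   taxon never rebinds it; the pass is strictly forward. A taxon seen
   before any date in the corpus yields a triplet with a missing date plus
   an `undated_entry` warning rather than being dropped.

Absence records ("the entire absence of robins…") are first-class: a
`status=absent` argument on the taxon template, or membership in a
configured `(page, verbatim)` absence list for legacy corpora whose
markup predates the status argument, flags the triplet. Flagged triplets
are excluded from default output and exported with
`occurrenceStatus=absent` when requested.

## Template grammar and linting

The grammar is deliberately flat: exactly two positional, pipe-separated
arguments, no nesting, whitespace-tolerant inside the braces. Anything
that fails it becomes a structured `ParseIssue` — never a silent drop —
with codes for unbalanced braces, missing arguments, near-miss template
names (edit distance 1 from a known kind), unparseable dates, undated
leading taxa, formal/verbatim date conflicts, and possible missed
annotations (capitalized terms matching already-annotated vocabulary
outside any template). The last two codes extend the core error taxonomy
because proofreading needs them: the canonical transcription error in this
material is a date template whose interpreted value contradicts its own
verbatim text (e.g. "Apl 5/07" interpreted as April 7, 1907), which only a
formal-vs-verbatim comparison can catch.

Parsing is position-faithful: each annotation records the half-open span
of its raw template text, so slicing the page by spans reproduces the
markup byte-for-byte — the property the suite checks with generated pages.

## Date normalization

Hand-written era dates come in a closed set of shapes: full month-name
dates, weekday-prefixed dates, month-abbreviation + slash two-digit-year
forms ("Apl 5/07", with "Apl" and "Sept" as period spellings), ISO dates
in the formal slot, and month- or year-only forms (returned at reduced
precision). Two-digit years are century-resolved inside the notebook's
configured date range; with no range configured the 1900s are assumed.
Calendar validity is enforced (June 31 fails). The formal slot is
normalized first, falling back to the verbatim slot; the exported
`verbatimEventDate` always carries the notebook's own wording.

## Taxonomic referencing

Names are normalized for matching: "[sic]" removed, editorial brackets
unwrapped ("[American] Robins" keeps "American"), whitespace collapsed,
lowercased, and the head noun singularized by a trivial suffix rule
(final "s" dropped unless the word ends in "ss"/"us"/"is", which protects
Latin endings). Each query is then matched independently against two
offline authority snapshots:

* exact scientific match: score 1.0;
* exact vernacular match: score 0.9, mapped to its scientific record;
* fuzzy scientific match within an edit-distance threshold (default 2):
  score `1 − d / max(|query|, |name|)` (edlib distances); fuzzy
  vernacular matching is opt-in (recommended threshold 1) because
  vernacular resolution is the error-prone path.

Ties rank accepted records first, then by identifier. A top-score tie
across *distinct* names (a vernacular shared by 18 species) makes that
authority's best candidate ambiguous rather than arbitrary. Candidate
identity includes kingdom, so cross-kingdom homonyms (*Crucibulum*:
gastropod vs fungus) can never be declared consistent. The two best
candidates classify the query into four consensus classes: consistent,
authority-A preferred, authority-B preferred, unresolved. Disagreements
are settled only by an external expert decisions file (query → A / B /
both / neither); without a decision the query stays unresolved and is
flagged for review. The numeric score is this package's concrete stand-in
for the opaque "probability scores" of live name-resolution services, and
is documented as such in the provenance output. For consistent results,
higher taxonomy and the preferred vernacular are taken from the
identifier-bearing (ITIS-like) snapshot when it participated, since its
serial numbers anchor those fields.

## Darwin Core export

One in-memory record list feeds all three outputs, so they cannot drift:
a simple CSV of standard terms, a full CSV appending provenance columns
(verbatim identification, resolution method and score, consensus class,
per-authority identifiers, carried flags — the provenance that standard
Darwin Core cannot express), and a Darwin Core Archive whose `meta.xml`
is generated from the same single field manifest that defines the record
layout. Unresolved names are published, not dropped: the record keeps the
annotator's formal name with `identificationRemarks` noting the
unresolved state. `recordedBy` and `basisOfRecord` are run-constant.

Catalog numbers are per-notebook sequences; `occurrenceID` is a SHA-1
hash of (notebook, page number, character offset). Page revision is
deliberately *not* hashed: extraction must be re-runnable as a notebook
grows, and hashing the revision would renumber every record on a page
whenever one annotation is added. The revision is instead carried in the
`references` permalink of each record.

## The synthetic-notebook generator

The generator emulates the structure of an annotated early-1900s
naturalist's notebook: blank-line-separated entries laid across pages,
most entries opened by a location + date header, taxa inline in short
prose sentences, entries occasionally split across page boundaries,
occasional absence records, occasional malformed templates (unclosed
braces). Defaults reflect the annotated pilot corpus this design targets:
~0.6 entries per page, a taxa-per-entry distribution supported on 0–33,
day-precision dates inside a configured notebook range, and a resolution
class mix of 52/18/8/22% (consistent / A-preferred / B-preferred /
unresolved). Exact counts (entries, taxa, dates, locations, absences,
per-class quotas) can be pinned, which the acceptance script uses to run
the pipeline at full annotated-corpus scale: three notebooks, 352 pages,
222 entries, 1,087 taxon annotations, with 11 absences and 8
manually-excluded annotations leaving 1,068 valid observations, and class
quotas 560/195/83/238 over the 1,076 referenced queries. Taxon names are
drawn from the bundled snapshots per intended class, so the referencing
outcome of every query is known at generation time yet still computed
end-to-end at run time.

What the generator does *not* emulate: handwriting/OCR noise, annotator
disagreement about interpretation, free-form header wording beyond the
implemented date styles, georeferenceable locality structure, or prose
that mentions taxa without annotating them (beyond the linter's
vocabulary heuristic). Passing tests therefore demonstrate correctness of
parsing, segmentation, grouping, referencing and export on well-formed
and known-malformed markup — not robustness to arbitrary transcription
noise.

## Numerical and design choices

* Entry excerpts are capped at 200 characters (configurable) — enough
  context to recognize the entry without duplicating the page.
* The corpus XML stores markup as escaped character data; round-tripping
  is exact for any XML-representable text (checked property-wise).
* Fixture transports make the whole suite network-free; the live
  MediaWiki transport is exercised only by end users running `fetch`.
* Test problem sizes — 100 five-page notebooks for the ground-truth
  equivalence property, 40 for malformation reporting, 25 for the
  backward-scan oracle — keep the default suite around a second while
  covering cross-page splits, absences and every resolution class; the
  full-scale (352-page) configuration runs in the acceptance script.
* Known limitations: the forward pass cannot represent retrospective
  entries ("yesterday at the lake…"); multi-locality entries bind taxa
  only to the most recent location; vernacular plural handling is a rule
  list, not a morphological analyser; and the authority snapshots are
  small synthetic stand-ins whose coverage is nothing like a real
  checklist's.
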