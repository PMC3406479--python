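# wikifieldnotes

Turn annotated wiki-markup transcriptions of historical field notebooks
into publishable Darwin Core species-occurrence record sets — without
losing the link back to the page, revision, and wording they came from.

Historical field notebooks are a major untapped source of species
occurrence baselines: dated, placed, first-person observations, often a
century old. When such notebooks are transcribed on a MediaWiki platform,
volunteers can mark up each observation inline with three small templates:

```
{{taxon|Sayornis saya|Say Phoebe}}
{{location|Boulder, Colorado|Boulder, Colo}}
{{date|1905-07-28|July 28, 1905}}
```

i.e. `{{kind|formal interpretation|text as written}}`. This package is the
post-processing side of that workflow, aimed at biodiversity informaticians
and collections staff mobilizing legacy notebooks:

1. **ingest** — fetch page wikitext from a MediaWiki-compatible API (or
   replayed fixtures), pin every page to a revision with a permalink, and
   persist the notebook as a single page-ordered XML corpus;
2. **annotation** — parse the template grammar into typed annotations with
   exact source spans, normalize era date forms ("July 28, 1905",
   "Sunday, June 10, 1906", "Apl 5/07"), and lint pages for the recurring
   transcription error shapes (unbalanced braces, formal/verbatim date
   conflicts, possible missed annotations);
3. **extraction** — concatenate pages so entries that cross page breaks
   stay whole, segment the notebook into blank-line-delimited entries, and
   run a single forward pass that couples every taxon annotation with the
   last date and last location seen (`taxon × date × location` triplets,
   with *carried* flags when an element is inherited from an earlier
   entry);
4. **referencing** — resolve each formal name (scientific or vernacular)
   against two offline name-authority snapshots independently, classify
   the consensus (consistent / one authority preferred / unresolved),
   and attach identifiers, vernacular names and higher taxonomy; expert
   adjudications live in a reviewable decisions file, and homonyms across
   kingdoms are never auto-merged;
5. **dwc_export** — crosswalk to Darwin Core, assign stable occurrence IDs
   (a hash of notebook, page, and character offset, so re-extraction never
   renumbers existing records), and write a simple Darwin Core CSV, a
   full-provenance CSV, and a Darwin Core Archive (occurrence core +
   `meta.xml`);
6. **synthbook** — generate synthetic notebooks with known ground truth
   (entries, annotations, expected triplets, expected resolution classes)
   so the whole pipeline is testable offline.

## Worked example

```python
from wikifieldnotes import run_pipeline
from wikifieldnotes.synthbook import default_authorities, make_henderson_fixture

corpus, _ = make_henderson_fixture()
result = run_pipeline(corpus, *default_authorities())
for r in result.records:
    print(r.catalogNumber, r.scientificName, r.eventDate, r.verbatimLocality)
```

prints

```
henderson-demo-0001 Sayornis saya 1905-07-28 Boulder, Colo
henderson-demo-0002 Carduelis pinus 1905-07-28 Boulder, Colo
henderson-demo-0003 Turdus migratorius 1905-07-28 Boulder, Colo
henderson-demo-0004 Colaptes auratus 1905-07-28 Boulder, Colo
henderson-demo-0005 Populus 1906-06-10 Big Thompson Creek near Loveland
```

The first four records come from a single annotated sentence — one
location, one date, four taxa, all bound to the same observation event.
The fifth demonstrates cross-page grouping: its location and date sit at
the bottom of page 2 while the taxon sits on page 3, yet segmentation
keeps the entry whole and the forward pass binds all three. Every record
carries a `references` URL resolving to the exact page revision it was
extracted from.

More narrative walkthroughs live in `examples/` (template parsing,
cross-page grouping, taxonomic referencing including the "mouse" and
*Crucibulum* traps, and the full pipeline on a synthetic notebook).

A thin CLI mirrors the stages: `wikifieldnotes fetch | lint | extract |
reconcile | export | synth | run-all` (see `--help`).

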