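"""Parse the annotated first sentence of a field notebook.

Builds the hand-written worked-example corpus, parses page one, and prints
each annotation.  Expect six: one location, one date, four taxa — every
inline {{taxon|...}}, {{location|...}}, {{date|...}} template becomes one
typed annotation with its exact source span.
"""

from wikifieldnotes import parse_annotations
from wikifieldnotes.synthbook import make_henderson_fixture

corpus, _ = make_henderson_fixture()
page = corpus.pages[0]
print(f"Page 1 wikitext:\n{page.wikitext}")

annotations, issues = parse_annotations(page.wikitext, page.page_number)
print(f"{len(annotations)} annotations, {len(issues)} issues\n")
for ann in annotations:
    print(f"  {ann.kind:<9} formal={ann.formal!r:<35} verbatim={ann.verbatim!r}")

# The formal slot is the annotator's interpretation; the verbatim slot
# preserves the notebook's own wording (including editorial brackets).
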