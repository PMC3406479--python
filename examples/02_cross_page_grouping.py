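"""Group a taxon with a date and place from the previous page.

Notebook entries routinely run across page boundaries.  Pages are joined
into one document before segmentation, so an entry whose place and date
header sits at the bottom of one page still binds a taxon at the top of
the next.  Expect one triplet: Populus + 1906-06-10 + "Big Thompson Creek
near Loveland", with the taxon on page 3 and its header on page 2.
"""

from wikifieldnotes import extract_from_corpus
from wikifieldnotes.synthbook import make_henderson_fixture

corpus, _ = make_henderson_fixture()
triplets, entries, issues = extract_from_corpus(corpus)

print(f"{len(entries)} entries, {len(triplets)} occurrence triplets\n")
last = triplets[-1]
print(f"taxon    : {last.taxon.formal} (page {last.page_number})")
print(f"date     : {last.event_date.iso}")
print(f"locality : {last.locality.verbatim} (page {last.locality.page_number})")
print(f"entry spans pages {entries[-1].start_page}-{entries[-1].end_page}")

# date_carried / locality_carried stay False here: all three elements
# belong to the same entry, even though it crosses a page break.
print(f"carried flags: date={last.date_carried}, locality={last.locality_carried}")
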