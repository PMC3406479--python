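"""Resolve annotators' names against two offline name authorities.

Queries mix scientific names, vernaculars and editorial brackets.  Each is
matched independently against an EOL-like and an ITIS-like snapshot;
agreement on the accepted name (and kingdom) yields a consistent
resolution, disagreement is surfaced for expert review, and a miss in both
stays unresolved.  Note the two classic traps: "mouse" (moth vs rodent)
and "Crucibulum" (fungus vs gastropod homonym) are flagged, never merged.
"""

from wikifieldnotes import attach_taxonomy, reconcile
from wikifieldnotes.synthbook import default_authorities

eol, itis = default_authorities()
queries = ["Sayornis saya", "[American] Robins", "siskins", "mouse",
           "Crucibulum", "Selasphorus platycercus", "Fictusaurus nullius"]

for query in queries:
    res = attach_taxonomy(reconcile(query, eol, itis), eol, itis)
    accepted = res.accepted_name or "-"
    review = " (needs review)" if res.review_needed else ""
    print(f"{query:<26} -> {accepted:<24} {res.consensus:<24}"
          f" via {res.resolution_method}{review}")
    if res.higher_taxonomy:
        print(f"{'':<26}    {res.higher_taxonomy.get('class', '?')}"
              f" / {res.higher_taxonomy.get('family', '?')}"
              f" | vernacular: {res.vernacular_name}")
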