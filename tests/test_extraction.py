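import pytest

from wikifieldnotes.annotation import IssueCode, parse_annotations
from wikifieldnotes.extraction import (
    ExtractionConfig,
    concatenate_pages,
    extract_from_corpus,
    split_entries,
    write_occurrence_csv,
    OCCURRENCE_CSV_COLUMNS,
)
from wikifieldnotes.synthbook import SynthConfig, generate_notebook

from conftest import make_corpus


def triplet_key(t):
    return (t.taxon.formal, t.taxon.verbatim,
            t.event_date.iso if t.event_date else None,
            t.locality.verbatim if t.locality else None,
            t.date_carried, t.locality_carried,
            t.page_number, t.occurrence_status)


class TestConcatenate:
    def test_single_page_is_identity(self):
        corpus = make_corpus(["only page"])
        document, _ = concatenate_pages(corpus)
        assert document == "only page"

    def test_pages_joined_by_single_newline(self):
        corpus = make_corpus(["end of page one", "start of page two"])
        document, _ = concatenate_pages(corpus)
        assert document == "end of page one\nstart of page two"

    def test_offset_map_round_trip_exhaustive(self):
        corpus = make_corpus(["abc", "", "defgh", "x"])
        document, offset_map = concatenate_pages(corpus)
        for offset in range(len(document) + 1):
            page, page_offset = offset_map.to_page(offset)
            assert offset_map.to_document(page, page_offset) == offset


class TestSplitEntries:
    def test_blank_line_separates_entries(self):
        corpus = make_corpus(["first entry text\n\nsecond entry text"])
        document, offset_map = concatenate_pages(corpus)
        entries = split_entries(document, offset_map)
        assert len(entries) == 2
        assert entries[0].text == "first entry text"
        assert entries[1].text == "second entry text"

    def test_whitespace_only_lines_are_blank(self):
        corpus = make_corpus(["a\n \t \nb\n\n\n\nc"])
        document, offset_map = concatenate_pages(corpus)
        assert len(split_entries(document, offset_map)) == 3

    def test_cross_page_entry_stays_whole(self):
        corpus = make_corpus(["entry starts here and", "continues on next page"])
        document, offset_map = concatenate_pages(corpus)
        entries = split_entries(document, offset_map)
        assert len(entries) == 1
        assert entries[0].start_page == 1 and entries[0].end_page == 2

    def test_empty_document(self):
        corpus = make_corpus(["", ""])
        document, offset_map = concatenate_pages(corpus)
        assert split_entries(document, offset_map) == []

    def test_entry_count_matches_generator_truth(self, authorities):
        config = SynthConfig(seed=11, n_pages=10, n_entries=25)
        corpus, truth = generate_notebook(config, authorities)
        document, offset_map = concatenate_pages(corpus)
        assert len(split_entries(document, offset_map)) == truth.n_entries == 25


class TestExtractOccurrences:
    def test_first_sentence_yields_four_bound_triplets(self, henderson):
        corpus, _ = henderson
        triplets, _, issues = extract_from_corpus(corpus)
        assert issues == []
        first = triplets[:4]
        assert len(first) == 4
        assert all(t.event_date.iso == "1905-07-28" for t in first)
        assert all(t.locality.verbatim == "Boulder, Colo" for t in first)
        assert all(not t.date_carried and not t.locality_carried for t in first)

    def test_cross_page_grouping(self, henderson):
        corpus, _ = henderson
        triplets, _, _ = extract_from_corpus(corpus)
        last = triplets[-1]
        assert last.taxon.formal == "Populus"
        assert last.event_date.iso == "1906-06-10"
        assert last.locality.verbatim == "Big Thompson Creek near Loveland"
        assert last.page_number == 3
        assert "oldid=demo003" in last.source_permalink

    def test_entry_without_taxa_yields_nothing(self):
        corpus = make_corpus([
            "{{location|Ward, Colorado|Ward}}. {{date|1906-05-01|May 1, 1906}}. "
            "Nothing seen today."
        ])
        triplets, _, issues = extract_from_corpus(corpus)
        assert triplets == [] and issues == []

    def test_state_carries_across_entries_with_flags(self):
        corpus = make_corpus([
            "{{location|Ward, Colorado|Ward}}. {{date|1906-05-01|May 1, 1906}}. "
            "Saw {{taxon|Corvus corax|ravens}}.\n"
            "\n"
            "Saw {{taxon|Pica hudsonia|magpies}} again, no header."
        ])
        triplets, _, _ = extract_from_corpus(corpus)
        raven, magpie = triplets
        assert not raven.date_carried and not raven.locality_carried
        assert magpie.date_carried and magpie.locality_carried
        assert magpie.event_date.iso == "1906-05-01"
        assert magpie.locality.verbatim == "Ward"

    def test_taxon_before_any_date_warns(self):
        corpus = make_corpus(["Saw {{taxon|Corvus corax|ravens}} first thing."])
        triplets, _, issues = extract_from_corpus(corpus)
        assert triplets[0].event_date is None
        assert any(i.code == IssueCode.UNDATED_ENTRY for i in issues)

    def test_absence_excluded_by_default(self):
        corpus = make_corpus([
            "{{location|Ward, Colorado|Ward}}. {{date|1906-05-01|May 1, 1906}}. "
            "Perplexed by the entire absence of "
            "{{taxon|Turdus migratorius|robins|status=absent}} on this trip."
        ])
        triplets, _, _ = extract_from_corpus(corpus)
        assert triplets == []
        triplets, _, _ = extract_from_corpus(
            corpus, ExtractionConfig(include_absences=True))
        assert len(triplets) == 1
        assert triplets[0].occurrence_status == "absent"

    def test_absence_list_flags_legacy_annotations(self):
        corpus = make_corpus([
            "{{location|Ward, Colorado|Ward}}. {{date|1906-05-01|May 1, 1906}}. "
            "Saw {{taxon|Corvus corax|ravens}} and {{taxon|Pica hudsonia|magpies}}."
        ])
        config = ExtractionConfig(absence_list={(1, "ravens")})
        triplets, _, _ = extract_from_corpus(corpus, config)
        assert [t.taxon.formal for t in triplets] == ["Pica hudsonia"]

    def test_excerpt_is_prefix_of_entry(self, authorities):
        config = SynthConfig(seed=5, n_pages=6)
        corpus, _ = generate_notebook(config, authorities)
        triplets, entries, _ = extract_from_corpus(
            corpus, ExtractionConfig(include_absences=True,
                                     year_range=config.year_range))
        by_index = {e.entry_index: e for e in entries}
        for t in triplets:
            entry = next(e for e in entries
                         if e.start_page <= t.page_number <= e.end_page
                         and t.entry_excerpt == e.text[:len(t.entry_excerpt)])
            assert entry.text.startswith(t.entry_excerpt)

    def test_determinism(self, authorities):
        config = SynthConfig(seed=7, n_pages=6)
        corpus, truth = generate_notebook(config, authorities)
        kwargs = ExtractionConfig(include_absences=True,
                                  absence_list=truth.exclusion_list,
                                  year_range=config.year_range)
        first = [triplet_key(t) for t in extract_from_corpus(corpus, kwargs)[0]]
        second = [triplet_key(t) for t in extract_from_corpus(corpus, kwargs)[0]]
        assert first == second


def brute_force_backward_scan(corpus, year_range):
    """Independent oracle: for each present taxon annotation, scan backwards
    through all annotations for the nearest preceding date and location."""
    from wikifieldnotes.annotation import normalize_date
    from wikifieldnotes.extraction import concatenate_pages

    document, offset_map = concatenate_pages(corpus)
    annotations = []
    for page in corpus.pages:
        anns, _ = parse_annotations(page.wikitext, page.page_number)
        start = offset_map.to_document(page.page_number, 0)
        annotations.extend(a.shifted(start) for a in anns)
    annotations.sort(key=lambda a: a.char_span[0])

    results = []
    for i, ann in enumerate(annotations):
        if ann.kind != "taxon":
            continue
        date = location = None
        for prev in reversed(annotations[:i]):
            if prev.kind == "date" and date is None:
                date = normalize_date(prev.formal, year_range).iso
            if prev.kind == "location" and location is None:
                location = prev.verbatim
            if date is not None and location is not None:
                break
        results.append((ann.formal, ann.verbatim, date, location,
                        ann.page_number))
    return results


@pytest.mark.parametrize("seed", range(25))
def test_forward_pass_equals_backward_scan_oracle(seed, authorities):
    """The stateful forward pass and a per-taxon backward scan must agree."""
    config = SynthConfig(seed=seed, n_pages=5, cross_page_split_prob=0.4,
                         absence_rate=0.1)
    corpus, _ = generate_notebook(config, authorities)
    triplets, _, _ = extract_from_corpus(
        corpus, ExtractionConfig(include_absences=True,
                                 year_range=config.year_range))
    got = [(t.taxon.formal, t.taxon.verbatim,
            t.event_date.iso if t.event_date else None,
            t.locality.verbatim if t.locality else None, t.page_number)
           for t in triplets]
    assert got == brute_force_backward_scan(corpus, config.year_range)


def test_occurrence_csv_round_trip(tmp_path, henderson):
    import csv

    corpus, _ = henderson
    triplets, _, _ = extract_from_corpus(corpus)
    path = tmp_path / "occ.csv"
    write_occurrence_csv(triplets, path)
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    assert len(rows) == len(triplets)
    assert list(rows[0]) == OCCURRENCE_CSV_COLUMNS
    assert rows[0]["taxon_formal"] == "Sayornis saya"
    assert rows[4]["event_date"] == "1906-06-10"
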