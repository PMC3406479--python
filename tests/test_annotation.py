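import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wikifieldnotes.annotation import (
    IssueCode,
    lint_page,
    normalize_date,
    parse_annotations,
)
from wikifieldnotes.errors import DateParseError


class TestParseAnnotations:
    @pytest.mark.parametrize(
        "markup, kind, formal, verbatim",
        [
            ("{{taxon|Sayornis saya|Say Phoebe}}", "taxon",
             "Sayornis saya", "Say Phoebe"),
            ("{{taxon|Carduelis pinus|siskins}}", "taxon",
             "Carduelis pinus", "siskins"),
            ("{{location|Boulder, Colorado|Boulder, Colo}}", "location",
             "Boulder, Colorado", "Boulder, Colo"),
            ("{{date|1905-07-28|July 28, 1905}}", "date",
             "1905-07-28", "July 28, 1905"),
            ("{{ taxon | Sayornis saya | Say Phoebe }}", "taxon",
             "Sayornis saya", "Say Phoebe"),  # whitespace-tolerant
        ],
    )
    def test_well_formed_template(self, markup, kind, formal, verbatim):
        anns, issues = parse_annotations(markup, 1)
        assert issues == []
        (ann,) = anns
        assert (ann.kind, ann.formal, ann.verbatim) == (kind, formal, verbatim)
        assert ann.status == "present"

    def test_empty_page(self):
        assert parse_annotations("", 1) == ([], [])

    def test_unbalanced_braces_reported_not_dropped(self):
        anns, issues = parse_annotations("{{taxon|Robin|robins", 1)
        assert anns == []
        assert [i.code for i in issues] == [IssueCode.UNBALANCED_BRACES]
        assert issues[0].severity == "error"

    def test_first_sentence_yields_six_annotations(self, henderson):
        corpus, _ = henderson
        anns, issues = parse_annotations(corpus.pages[0].wikitext, 1)
        assert issues == []
        kinds = [a.kind for a in anns]
        assert len(anns) == 6
        assert kinds.count("location") == 1
        assert kinds.count("date") == 1
        assert kinds.count("taxon") == 4

    def test_absence_status_parsed(self):
        anns, issues = parse_annotations(
            "{{taxon|Turdus migratorius|robins|status=absent}}", 1)
        assert issues == []
        assert anns[0].status == "absent"

    def test_missing_argument(self):
        anns, issues = parse_annotations("{{taxon|Siskin}}", 1)
        assert anns == []
        assert issues[0].code == IssueCode.MISSING_ARGUMENT

    def test_excess_arguments_rejected(self):
        anns, issues = parse_annotations("{{taxon|a|b|c}}", 1)
        assert anns == []
        assert issues[0].code == IssueCode.MISSING_ARGUMENT

    def test_typo_template_warned(self):
        anns, issues = parse_annotations("{{taxn|Populus|cottonwood}}", 1)
        assert anns == []
        assert issues[0].code == IssueCode.UNKNOWN_TEMPLATE
        assert issues[0].severity == "warning"

    def test_unrelated_template_ignored(self):
        anns, issues = parse_annotations("{{Unbalanced}} prose {{cite|x|y}}", 1)
        assert anns == [] and issues == []

    def test_positions_are_faithful(self, henderson):
        corpus, _ = henderson
        for page in corpus.pages:
            anns, _ = parse_annotations(page.wikitext, page.page_number)
            for ann in anns:
                lo, hi = ann.char_span
                assert page.wikitext[lo:hi] == ann.raw

    def test_parse_serialize_round_trip(self, henderson):
        """Inter-annotation text + raw template text rebuilds the page."""
        corpus, _ = henderson
        for page in corpus.pages:
            anns, _ = parse_annotations(page.wikitext, page.page_number)
            rebuilt, pos = [], 0
            for ann in anns:
                rebuilt.append(page.wikitext[pos:ann.char_span[0]])
                rebuilt.append(ann.raw)
                pos = ann.char_span[1]
            rebuilt.append(page.wikitext[pos:])
            assert "".join(rebuilt) == page.wikitext

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.sampled_from([
        "{{taxon|Pica hudsonia|magpies}}",
        "{{location|Ward, Colorado|Ward}}",
        "{{date|1906-05-01|May 1, 1906}}",
        "prose with no markup. ",
        "\n\n",
    ]), max_size=12))
    def test_document_order_and_spans(self, pieces):
        text = "".join(pieces)
        anns, issues = parse_annotations(text, 1)
        assert issues == []
        expected = sum(1 for p in pieces if p.startswith("{{"))
        assert len(anns) == expected
        spans = [a.char_span for a in anns]
        assert spans == sorted(spans)
        for ann in anns:
            assert text[ann.char_span[0]:ann.char_span[1]] == ann.raw


class TestNormalizeDate:
    @pytest.mark.parametrize(
        "text, iso, precision",
        [
            ("July 28, 1905", "1905-07-28", "day"),
            ("Sunday, June 10, 1906", "1906-06-10", "day"),
            ("Apl 5/07", "1907-04-05", "day"),
            ("Sept 3/06", "1906-09-03", "day"),
            ("1905-07-28", "1905-07-28", "day"),
            ("July 1905", "1905-07", "month"),
            ("1905", "1905", "year"),
            ("Jan. 2, 1909", "1909-01-02", "day"),
        ],
    )
    def test_known_forms(self, text, iso, precision):
        nd = normalize_date(text, year_range=(1905, 1909))
        assert (nd.iso, nd.precision) == (iso, precision)
        assert nd.source_text == text

    def test_century_resolved_by_notebook_range(self):
        assert normalize_date("Apl 5/07", (1905, 1907)).iso == "1907-04-05"
        assert normalize_date("Jan 5/06", (2004, 2008)).iso == "2006-01-05"

    @pytest.mark.parametrize("text", ["banana", "", "32 Nevember", "June 31, 1905"])
    def test_unparseable_raises(self, text):
        with pytest.raises(DateParseError):
            normalize_date(text)


class TestLintPage:
    def test_clean_page_has_no_errors(self, henderson):
        corpus, _ = henderson
        issues = lint_page(corpus.pages[0].wikitext, 1, year_range=(1905, 1907))
        assert [i for i in issues if i.severity == "error"] == []

    def test_formal_verbatim_date_conflict_flagged(self):
        # the documented mis-annotation: "Apl 5/07" interpreted as April 7
        issues = lint_page("{{date|1907-04-07|Apl 5/07}}", 12,
                           year_range=(1905, 1907))
        assert any(i.code == IssueCode.DATE_CONFLICT for i in issues)

    def test_consistent_date_not_flagged(self):
        issues = lint_page("{{date|1907-04-05|Apl 5/07}}", 12,
                           year_range=(1905, 1907))
        assert issues == []

    def test_unbalanced_template_is_one_error(self):
        issues = lint_page("{{taxon|Robin|robins", 3)
        errors = [i for i in issues if i.severity == "error"]
        assert len(errors) == 1
        assert errors[0].code == IssueCode.UNBALANCED_BRACES

    def test_possible_missed_annotation_warned(self):
        text = ("{{taxon|Turdus migratorius|Robins}} seen at dawn. "
                "More Robins in the afternoon.")
        issues = lint_page(text, 1)
        missed = [i for i in issues
                  if i.code == IssueCode.POSSIBLE_MISSED_ANNOTATION]
        assert len(missed) == 1
        assert missed[0].severity == "warning"
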