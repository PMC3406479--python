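import pytest

from wikifieldnotes.ingest import FixtureTransport, NotebookRef, PageCorpus, RawPage
from wikifieldnotes.synthbook import default_authorities, make_henderson_fixture


@pytest.fixture(scope="session")
def authorities():
    return default_authorities()


@pytest.fixture()
def henderson():
    """Worked-example corpus: first-sentence entry + cross-page entry."""
    return make_henderson_fixture()


@pytest.fixture()
def fixture_transport():
    return FixtureTransport(
        indexes={
            "Index:demo": ["Page:demo/1", "Page:demo/2", "Page:demo/3"],
            "Index:empty": [],
        },
        pages={
            "Page:demo/1": {
                "r1": "{{taxon|Sayornis saya|Say Phoebe}}",
                "r2": "{{taxon|Sayornis saya|Say Phoebe}} edited later",
            },
            "Page:demo/2": {"r1": ""},
            "Page:demo/3": {"r1": "plain prose, no templates"},
        },
    )


def make_corpus(texts: list[str], notebook_id: str = "nb") -> PageCorpus:
    """Corpus-from-strings helper shared across test modules."""
    pages = [
        RawPage(
            page_number=i,
            title=f"Page:{notebook_id}/{i}",
            revision_id=f"r{i}",
            timestamp="2020-01-01T00:00:00+00:00",
            permalink=f"https://example.org/w/index.php?title=Page:{notebook_id}/{i}&oldid=r{i}",
            wikitext=text,
        )
        for i, text in enumerate(texts, start=1)
    ]
    ref = NotebookRef(notebook_id, f"Index:{notebook_id}",
                      page_titles=[p.title for p in pages])
    return PageCorpus(ref, pages)
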