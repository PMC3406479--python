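"""Acquire notebook page wikitext and persist page-ordered corpora.

A notebook lives on a MediaWiki-compatible host as an index page plus one
wiki page per scanned notebook page.  Occurrence extraction must always
reference the exact revision of each page that was read, so every fetched
page is pinned to a revision and carries a permalink resolving to that
revision.  A fetched notebook is persisted as a single XML document (one
``<page>`` element per notebook page, in page order) so downstream stages
are reproducible and network-free.

Transports are pluggable: :class:`MediaWikiTransport` speaks the live
action API over HTTP; :class:`FixtureTransport` replays recorded responses
and is what the test suite uses throughout.
"""

from __future__ import annotations

import datetime as _dt
import json
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from typing import Protocol

from lxml import etree

from .errors import ConfigurationError, CorpusFormatError, IngestError

__all__ = [
    "NotebookRef",
    "RawPage",
    "PageCorpus",
    "Transport",
    "FixtureTransport",
    "MediaWikiTransport",
    "fetch_page_count",
    "fetch_page",
    "fetch_corpus",
    "dump_corpus",
    "load_corpus",
]


@dataclass
class NotebookRef:
    """Identity of one notebook: its index page and the ordered page titles."""

    notebook_id: str
    index_title: str
    page_titles: list[str] = field(default_factory=list)
    revision_pins: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if not self.page_titles:
            raise ConfigurationError(f"notebook {self.notebook_id!r}: empty page list")
        if len(set(self.page_titles)) != len(self.page_titles):
            raise ConfigurationError(f"notebook {self.notebook_id!r}: duplicate page titles")
        for title in self.revision_pins:
            if title not in self.page_titles:
                raise ConfigurationError(
                    f"notebook {self.notebook_id!r}: revision pin for unknown page {title!r}"
                )


@dataclass
class RawPage:
    """One notebook page's wikitext, pinned to a revision.

    ``page_number`` is the 1-based ordinal within the notebook (matching the
    scanned page labels); ``permalink`` resolves to exactly ``revision_id``.
    Blank notebook pages are legal: ``wikitext`` may be empty.
    """

    page_number: int
    title: str
    revision_id: str
    timestamp: str
    permalink: str
    wikitext: str

    def __post_init__(self) -> None:
        if self.page_number < 1:
            raise ValueError("page_number must be >= 1")


@dataclass
class PageCorpus:
    """A whole notebook: metadata plus pages ordered by page_number."""

    notebook: NotebookRef
    pages: list[RawPage]

    def validate(self) -> None:
        numbers = [p.page_number for p in self.pages]
        if numbers != list(range(1, len(numbers) + 1)):
            raise CorpusFormatError(
                f"corpus {self.notebook.notebook_id!r}: page numbers {numbers} "
                "are not gap-free from 1"
            )

    def permalinks(self) -> dict[int, str]:
        return {p.page_number: p.permalink for p in self.pages}


class Transport(Protocol):
    """Read-only access to a wiki: index listing and per-page wikitext."""

    def list_index(self, index_title: str) -> list[str]:
        """Return the ordered page titles the index resolves to."""
        ...

    def get_page(self, title: str, pin: str | None) -> tuple[str, str, str] | None:
        """Return (wikitext, revision_id, permalink) or None if the page is missing."""
        ...


class FixtureTransport:
    """Recorded-response transport: replays a dict of canned pages.

    ``pages`` maps title -> {revision_id: wikitext}; ``indexes`` maps
    index title -> ordered page titles.  Fetching an unpinned title returns
    the highest revision (lexicographic, mirroring monotone revision ids).
    """

    def __init__(
        self,
        indexes: dict[str, list[str]],
        pages: dict[str, dict[str, str]],
        base_url: str = "https://example.org/w/index.php",
    ):
        self.indexes = indexes
        self.pages = pages
        self.base_url = base_url

    def list_index(self, index_title: str) -> list[str]:
        if index_title not in self.indexes:
            raise ConfigurationError(f"index page {index_title!r} not found")
        return list(self.indexes[index_title])

    def get_page(self, title: str, pin: str | None) -> tuple[str, str, str] | None:
        revs = self.pages.get(title)
        if not revs:
            return None
        if pin is None:
            pin = max(revs)
        if pin not in revs:
            raise IngestError(f"revision {pin!r} of page {title!r} not found")
        quoted = urllib.parse.quote(title.replace(" ", "_"))
        permalink = f"{self.base_url}?title={quoted}&oldid={pin}"
        return revs[pin], pin, permalink


class MediaWikiTransport:
    """Live HTTP transport for a MediaWiki action API endpoint.

    Only two read operations are used: listing the pages an index links to
    and fetching the raw wikitext of one revision.  This transport is never
    exercised by the test suite (which replays fixtures); it exists so the
    ``fetch`` subcommand can pull real notebooks when a network is present.
    """

    def __init__(self, api_url: str, user_agent: str = "wikifieldnotes/0.1"):
        self.api_url = api_url
        self.user_agent = user_agent

    def _call(self, params: dict[str, str]) -> dict:
        params = dict(params, format="json", formatversion="2")
        url = self.api_url + "?" + urllib.parse.urlencode(params)
        req = urllib.request.Request(url, headers={"User-Agent": self.user_agent})
        try:
            with urllib.request.urlopen(req, timeout=30) as resp:
                return json.loads(resp.read().decode("utf-8"))
        except OSError as exc:  # DNS, connect, timeout: all retryable
            raise IngestError(f"transport failure calling {self.api_url}: {exc}") from exc

    def list_index(self, index_title: str) -> list[str]:
        data = self._call(
            {"action": "query", "prop": "links", "titles": index_title, "pllimit": "max"}
        )
        pages = data.get("query", {}).get("pages", [])
        if not pages or pages[0].get("missing"):
            raise ConfigurationError(f"index page {index_title!r} not found")
        return [link["title"] for link in pages[0].get("links", [])]

    def get_page(self, title: str, pin: str | None) -> tuple[str, str, str] | None:
        params = {
            "action": "query",
            "prop": "revisions",
            "rvprop": "ids|content",
            "rvslots": "main",
        }
        if pin is not None:
            params["revids"] = str(pin)
        else:
            params["titles"] = title
        data = self._call(params)
        pages = data.get("query", {}).get("pages", [])
        if not pages or pages[0].get("missing"):
            return None
        rev = pages[0]["revisions"][0]
        revid = str(rev["revid"])
        text = rev["slots"]["main"]["content"]
        base = self.api_url.rsplit("/", 1)[0] + "/index.php"
        quoted = urllib.parse.quote(title.replace(" ", "_"))
        return text, revid, f"{base}?title={quoted}&oldid={revid}"


def fetch_page_count(notebook: NotebookRef, transport: Transport) -> int:
    """Resolve the notebook's index to its page list; return the page count.

    Populates ``notebook.page_titles`` in index order.  An index resolving
    to zero pages is a fatal configuration error (nothing to extract).
    """
    titles = transport.list_index(notebook.index_title)
    if not titles:
        raise ConfigurationError(
            f"index {notebook.index_title!r} lists no pages"
        )
    notebook.page_titles = titles
    notebook.validate()
    return len(titles)


def fetch_page(
    title: str,
    pin: str | None,
    transport: Transport,
    page_number: int = 1,
) -> RawPage:
    """Fetch one page's wikitext, pinned to ``pin`` or to latest-at-fetch.

    A missing page is recorded as an empty RawPage (blank notebook pages
    exist); a missing *revision* of an existing page is fatal and raised by
    the transport.
    """
    got = transport.get_page(title, pin)
    stamp = _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")
    if got is None:
        return RawPage(page_number, title, revision_id="", timestamp=stamp,
                       permalink="", wikitext="")
    wikitext, revision_id, permalink = got
    return RawPage(page_number, title, revision_id, stamp, permalink, wikitext)


def fetch_corpus(notebook: NotebookRef, transport: Transport) -> PageCorpus:
    """Fetch the whole notebook in index order, freezing revisions as found."""
    fetch_page_count(notebook, transport)
    pages = [
        fetch_page(title, notebook.revision_pins.get(title), transport, page_number=i)
        for i, title in enumerate(notebook.page_titles, start=1)
    ]
    corpus = PageCorpus(notebook, pages)
    corpus.validate()
    return corpus


_CORPUS_TAG = "notebook-corpus"


def dump_corpus(corpus: PageCorpus, path) -> None:
    """Serialize a corpus to one UTF-8 XML document; inverse of load_corpus.

    Markup is stored as escaped character data, so XML-reserved characters
    in wikitext round-trip exactly.
    """
    corpus.validate()
    root = etree.Element(
        _CORPUS_TAG,
        notebook_id=corpus.notebook.notebook_id,
        index_title=corpus.notebook.index_title,
        page_count=str(len(corpus.pages)),
    )
    for page in corpus.pages:
        el = etree.SubElement(
            root,
            "page",
            number=str(page.page_number),
            title=page.title,
            revision_id=page.revision_id,
            timestamp=page.timestamp,
            permalink=page.permalink,
        )
        el.text = page.wikitext
    etree.ElementTree(root).write(str(path), encoding="utf-8", xml_declaration=True)


def load_corpus(path) -> PageCorpus:
    """Parse a corpus XML file; fatal CorpusFormatError on any schema violation."""
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise CorpusFormatError(f"unreadable corpus file {path}: {exc}") from exc
    root = tree.getroot()
    if root.tag != _CORPUS_TAG:
        raise CorpusFormatError(f"root element is <{root.tag}>, expected <{_CORPUS_TAG}>")
    notebook = NotebookRef(
        notebook_id=root.get("notebook_id", ""),
        index_title=root.get("index_title", ""),
    )
    pages: list[RawPage] = []
    for el in root:
        if el.tag != "page":
            raise CorpusFormatError(f"unexpected element <{el.tag}> in corpus")
        try:
            number = int(el.get("number", ""))
        except ValueError:
            raise CorpusFormatError(f"page element with non-integer number {el.get('number')!r}")
        pages.append(
            RawPage(
                page_number=number,
                title=el.get("title", ""),
                revision_id=el.get("revision_id", ""),
                timestamp=el.get("timestamp", ""),
                permalink=el.get("permalink", ""),
                wikitext=el.text or "",
            )
        )
    declared = root.get("page_count")
    if declared is not None and int(declared) != len(pages):
        raise CorpusFormatError(
            f"corpus declares {declared} pages but contains {len(pages)}"
        )
    notebook.page_titles = [p.title for p in pages]
    corpus = PageCorpus(notebook, pages)
    corpus.validate()
    return corpus
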