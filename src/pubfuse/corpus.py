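"""Bibliographic records and MEDLINE XML ingestion.

A :class:`Corpus` is an ordered, id-unique collection of
:class:`ArticleRecord` objects.  Both the lexical and the semantic index
operate on the same *index text* — the concatenation ``title + " " + abstract``
— so the two retrieval modalities always see an identical view of each
document.

Records are read from PubMed/MEDLINE citation XML
(``PubmedArticleSet/PubmedArticle``) or constructed programmatically (see
:mod:`pubfuse.synthetic`).  A corpus round-trips bit-exactly through a
single-file JSON store with an explicit schema version.
"""

from __future__ import annotations

import io
import json
import logging
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

from lxml import etree

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

#: Shard key assigned to records without a resolvable 4-digit publication year.
UNKNOWN_YEAR = "unknown"

_WS_RE = re.compile(r"\s+")
_YEAR_RE = re.compile(r"\b(\d{4})\b")


class CorpusError(Exception):
    """Base error for corpus ingestion and storage."""


class CorpusParseError(CorpusError):
    """Malformed MEDLINE XML; carries the reported byte/line position."""


def normalize_text(text: str) -> str:
    """Unicode NFC + collapse runs of whitespace to a single space, strip ends."""
    return _WS_RE.sub(" ", unicodedata.normalize("NFC", text)).strip()


@dataclass(frozen=True)
class ArticleRecord:
    """One bibliographic record — the unit of indexing and retrieval.

    ``doc_id`` is the PMID for real data or a synthetic identifier; ``year``
    is ``None`` when no 4-digit publication year could be resolved, in which
    case the record belongs to the :data:`UNKNOWN_YEAR` lexical shard.
    """

    doc_id: str
    title: str
    abstract: str = ""
    year: int | None = None
    journal: str = ""
    authors: tuple[str, ...] = ()
    mesh_terms: tuple[str, ...] = ()
    doi: str | None = None

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")
        if not normalize_text(self.title):
            raise ValueError(f"record {self.doc_id!r}: title must be non-empty")
        if self.year is not None and not (1000 <= int(self.year) <= 9999):
            raise ValueError(f"record {self.doc_id!r}: year must be a 4-digit integer")

    @property
    def index_text(self) -> str:
        """Text seen by both the lexical and the semantic pipeline."""
        if self.abstract:
            return f"{self.title} {self.abstract}"
        return self.title

    @property
    def shard_key(self) -> str:
        return str(self.year) if self.year is not None else UNKNOWN_YEAR


@dataclass
class ParseReport:
    """Bookkeeping emitted by :func:`parse_pubmed_xml`."""

    n_parsed: int = 0
    n_dropped: int = 0
    duplicate_ids: list[str] = field(default_factory=list)


class Corpus:
    """Ordered collection of :class:`ArticleRecord` with unique ``doc_id``.

    Iteration order is the insertion order and is stable for a given input;
    adding a record whose id already exists replaces the earlier record in
    place (later record wins).
    """

    def __init__(self, records: Sequence[ArticleRecord] = ()) -> None:
        self._records: list[ArticleRecord] = []
        self._by_id: dict[str, int] = {}
        self.parse_report: ParseReport | None = None
        for rec in records:
            self.add(rec)

    def add(self, record: ArticleRecord) -> None:
        pos = self._by_id.get(record.doc_id)
        if pos is None:
            self._by_id[record.doc_id] = len(self._records)
            self._records.append(record)
        else:
            logger.warning("duplicate doc_id %s: later record wins", record.doc_id)
            self._records[pos] = record

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[ArticleRecord]:
        return iter(self._records)

    def __contains__(self, doc_id: str) -> bool:
        return doc_id in self._by_id

    def __getitem__(self, doc_id: str) -> ArticleRecord:
        try:
            return self._records[self._by_id[doc_id]]
        except KeyError:
            raise KeyError(f"unknown doc_id: {doc_id!r}") from None

    def doc_ids(self) -> list[str]:
        return [r.doc_id for r in self._records]

    def index_text(self, doc_id: str) -> str:
        return self[doc_id].index_text

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        return self._records == other._records


# ---------------------------------------------------------------------------
# MEDLINE XML ingestion
# ---------------------------------------------------------------------------

def _text(elem: etree._Element | None) -> str:
    if elem is None:
        return ""
    return normalize_text("".join(elem.itertext()))


def _extract_year(article: etree._Element) -> int | None:
    # Prefer PubDate/Year; fall back to the leading 4-digit year of a
    # MedlineDate string ("2019 Nov-Dec"); otherwise unresolved.
    year = article.findtext(".//Journal/JournalIssue/PubDate/Year")
    if year and year.strip().isdigit():
        return int(year.strip())
    medline_date = article.findtext(".//Journal/JournalIssue/PubDate/MedlineDate")
    if medline_date:
        m = _YEAR_RE.search(medline_date)
        if m:
            return int(m.group(1))
    return None


def _extract_authors(article: etree._Element) -> tuple[str, ...]:
    authors = []
    for author in article.findall(".//AuthorList/Author"):
        last = normalize_text(author.findtext("LastName") or "")
        initials = normalize_text(author.findtext("Initials") or "")
        if last and initials:
            authors.append(f"{last} {initials}")
        elif last:
            authors.append(last)
        else:
            collective = normalize_text(author.findtext("CollectiveName") or "")
            if collective:
                authors.append(collective)
    return tuple(authors)


def _parse_citation(citation: etree._Element) -> ArticleRecord | None:
    pmid = normalize_text(citation.findtext(".//PMID") or "")
    article = citation.find(".//Article")
    if article is None or not pmid:
        return None
    title = _text(article.find("ArticleTitle"))
    # Multiple AbstractText sections (structured abstracts) are concatenated
    # with a single space in document order.
    abstract = normalize_text(
        " ".join(_text(sec) for sec in article.findall(".//Abstract/AbstractText"))
    )
    if not title and not abstract:
        return None
    if not title:
        # Keep abstract-only records indexable: the record model requires a
        # non-empty title, so surface the abstract head as a stand-in title.
        title = abstract
    doi = None
    for eloc in article.findall("ELocationID"):
        if eloc.get("EIdType") == "doi" and _text(eloc):
            doi = _text(eloc)
    mesh = tuple(
        _text(d)
        for d in citation.findall(".//MeshHeadingList/MeshHeading/DescriptorName")
        if _text(d)
    )
    return ArticleRecord(
        doc_id=pmid,
        title=title,
        abstract=abstract,
        year=_extract_year(article),
        journal=_text(article.find(".//Journal/Title")),
        authors=_extract_authors(article),
        mesh_terms=mesh,
        doi=doi,
    )


def parse_pubmed_xml(source) -> Corpus:
    """Parse a PubMed/MEDLINE citation XML stream into a :class:`Corpus`.

    ``source`` may be a path, a file-like object, or raw bytes.  Citations
    lacking both a title and an abstract are dropped and counted in the
    corpus's :class:`ParseReport`; a duplicate PMID replaces the earlier
    record (later wins).  Malformed XML raises :class:`CorpusParseError`
    naming the reported position — no partial corpus is returned.
    """
    if isinstance(source, bytes):
        source = io.BytesIO(source)
    try:
        tree = etree.parse(source)
    except etree.XMLSyntaxError as exc:
        raise CorpusParseError(f"malformed MEDLINE XML: {exc}") from exc
    corpus = Corpus()
    report = ParseReport()
    for citation in tree.iter("PubmedArticle"):
        rec = _parse_citation(citation)
        if rec is None:
            report.n_dropped += 1
            continue
        if rec.doc_id in corpus:
            report.duplicate_ids.append(rec.doc_id)
        corpus.add(rec)
        report.n_parsed += 1
    corpus.parse_report = report
    return corpus


# ---------------------------------------------------------------------------
# Single-file record store (JSON, versioned)
# ---------------------------------------------------------------------------

def save_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write the corpus to a single JSON file (schema-versioned, UTF-8)."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "records": [
            {
                "doc_id": r.doc_id,
                "title": r.title,
                "abstract": r.abstract,
                "year": r.year,
                "journal": r.journal,
                "authors": list(r.authors),
                "mesh_terms": list(r.mesh_terms),
                "doi": r.doi,
            }
            for r in corpus
        ],
    }
    Path(path).write_text(
        json.dumps(payload, ensure_ascii=False, indent=None), encoding="utf-8"
    )


def load_corpus(path: str | Path) -> Corpus:
    """Load a corpus written by :func:`save_corpus`; inverse on all fields."""
    path = Path(path)
    if not path.exists():
        raise CorpusError(f"corpus store not found: {path}")
    payload = json.loads(path.read_text(encoding="utf-8"))
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise CorpusError(
            f"corpus store schema version {version!r} != expected {SCHEMA_VERSION}"
        )
    return Corpus(
        [
            ArticleRecord(
                doc_id=d["doc_id"],
                title=d["title"],
                abstract=d["abstract"],
                year=d["year"],
                journal=d["journal"],
                authors=tuple(d["authors"]),
                mesh_terms=tuple(d["mesh_terms"]),
                doi=d["doi"],
            )
            for d in payload["records"]
        ]
    )


__all__ = [
    "ArticleRecord",
    "Corpus",
    "CorpusError",
    "CorpusParseError",
    "ParseReport",
    "UNKNOWN_YEAR",
    "normalize_text",
    "parse_pubmed_xml",
    "save_corpus",
    "load_corpus",
]
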