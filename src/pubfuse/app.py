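"""Result filtering, facet aggregation, and export.

Post-retrieval conveniences: an AND-composed metadata filter (year range,
journal, author, MeSH membership) that never reorders results, a Top-10
facet summary over the retrieved set, and byte-stable CSV / BibTeX export.
"""

from __future__ import annotations

import csv
import io
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .corpus import ArticleRecord, Corpus
from .fusion import ScoredCandidate

CSV_HEADER = [
    "doc_id",
    "title",
    "abstract",
    "year",
    "journal",
    "authors",
    "doi",
    "fs",
    "bm2501",
    "cosim",
]

#: List-valued record fields are joined with this separator in CSV cells.
LIST_SEP = "; "


@dataclass(frozen=True)
class ResultFilter:
    """Conjunction of optional constraints; set constraints are OR-within."""

    year_min: int | None = None
    year_max: int | None = None
    journals: frozenset[str] | None = None
    authors: frozenset[str] | None = None
    mesh_terms: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if (
            self.year_min is not None
            and self.year_max is not None
            and self.year_min > self.year_max
        ):
            raise ValueError("year_min must not exceed year_max")

    def matches(self, rec: ArticleRecord) -> bool:
        if self.year_min is not None and (rec.year is None or rec.year < self.year_min):
            return False
        if self.year_max is not None and (rec.year is None or rec.year > self.year_max):
            return False
        if self.journals is not None and rec.journal not in self.journals:
            return False
        if self.authors is not None and not self.authors.intersection(rec.authors):
            return False
        if self.mesh_terms is not None and not self.mesh_terms.intersection(rec.mesh_terms):
            return False
        return True


def apply_filter(
    results: Sequence[ScoredCandidate], result_filter: ResultFilter, corpus: Corpus
) -> list[ScoredCandidate]:
    """Order-preserving subset of results whose records pass every constraint."""
    return [c for c in results if result_filter.matches(corpus[c.doc_id])]


@dataclass
class FacetSummary:
    """Top-10 (term, count) lists over the retrieved set, count-desc then A-Z."""

    top_mesh: list[tuple[str, int]] = field(default_factory=list)
    top_journals: list[tuple[str, int]] = field(default_factory=list)
    top_authors: list[tuple[str, int]] = field(default_factory=list)


def _top10(counter: Counter) -> list[tuple[str, int]]:
    return sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))[:10]


def compute_facets(results: Sequence[ScoredCandidate], corpus: Corpus) -> FacetSummary:
    """Count MeSH terms, journals, and authors over the retrieved set only."""
    mesh: Counter = Counter()
    journals: Counter = Counter()
    authors: Counter = Counter()
    for cand in results:
        rec = corpus[cand.doc_id]
        mesh.update(rec.mesh_terms)
        if rec.journal:
            journals[rec.journal] += 1
        authors.update(rec.authors)
    return FacetSummary(
        top_mesh=_top10(mesh),
        top_journals=_top10(journals),
        top_authors=_top10(authors),
    )


def _select(
    results: Sequence[ScoredCandidate], selection: Iterable[str] | None
) -> list[ScoredCandidate]:
    if selection is None:
        return list(results)
    wanted = set(selection)
    return [c for c in results if c.doc_id in wanted]


def _bibtex_escape(text: str) -> str:
    return text.replace("{", r"\{").replace("}", r"\}")


def _bibtex_author(name: str) -> str:
    # Records store "Last Initials"; BibTeX wants "Last, I.".
    parts = name.rsplit(" ", 1)
    if len(parts) == 2 and parts[1].isalpha() and parts[1].isupper():
        initials = ". ".join(parts[1]) + "."
        return f"{parts[0]}, {initials}"
    return name


def export_results(
    results: Sequence[ScoredCandidate],
    corpus: Corpus,
    format: str,
    selection: Iterable[str] | None = None,
) -> bytes:
    """Serialize (a selection of) results as UTF-8 CSV or BibTeX bytes.

    CSV uses the fixed documented header with RFC-4180 quoting; BibTeX emits
    one ``@article`` per record with citation key ``pmid<doc_id>``.  Output
    is byte-stable for fixed input.
    """
    chosen = _select(results, selection)
    if format == "csv":
        buf = io.StringIO()
        writer = csv.writer(buf, quoting=csv.QUOTE_MINIMAL, lineterminator="\r\n")
        writer.writerow(CSV_HEADER)
        for cand in chosen:
            rec = corpus[cand.doc_id]
            writer.writerow(
                [
                    rec.doc_id,
                    rec.title,
                    rec.abstract,
                    "" if rec.year is None else rec.year,
                    rec.journal,
                    LIST_SEP.join(rec.authors),
                    rec.doi or "",
                    repr(cand.fs),
                    repr(cand.bm2501),
                    repr(cand.cosim),
                ]
            )
        return buf.getvalue().encode("utf-8")
    if format == "bibtex":
        entries = []
        for cand in chosen:
            rec = corpus[cand.doc_id]
            fields = [("title", rec.title)]
            if rec.authors:
                fields.append(
                    ("author", " and ".join(_bibtex_author(a) for a in rec.authors))
                )
            if rec.journal:
                fields.append(("journal", rec.journal))
            if rec.year is not None:
                fields.append(("year", str(rec.year)))
            if rec.doi:
                fields.append(("doi", rec.doi))
            body = ",\n".join(
                f"  {key} = {{{_bibtex_escape(value)}}}" for key, value in fields
            )
            entries.append(f"@article{{pmid{rec.doc_id},\n{body}\n}}")
        return ("\n\n".join(entries) + "\n").encode("utf-8")
    raise ValueError(f"unsupported export format: {format!r}")


__all__ = [
    "CSV_HEADER",
    "LIST_SEP",
    "ResultFilter",
    "FacetSummary",
    "apply_filter",
    "compute_facets",
    "export_results",
]
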