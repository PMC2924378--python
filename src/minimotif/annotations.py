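"""Protein accession -> GO term-set maps, with alias resolution.

The minimotif database and GO annotation sets may record the same
protein under different accession numbers, so term lookup goes through
an alias table (alias -> canonical accession, identity fallback).
Annotations are read from GAF 2.x association files; only rows whose
aspect column matches the target namespace contribute, NOT-qualified
rows are skipped, and terms absent from the companion ontology graph
are dropped (counted, for diagnostics).

Annotations are *not* propagated upward to ancestor terms: the distance
computation in the filters supplies the generalisation, and pre-
propagating would make every shared-term test succeed trivially at the
namespace root.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

from .ontology import OntologyGraph

__all__ = [
    "GafParseError",
    "AliasTable",
    "AnnotationSet",
    "parse_gaf",
    "parse_alias_table",
    "resolve",
    "terms_for",
]

logger = logging.getLogger(__name__)

#: GAF aspect column -> GO namespace.
ASPECT_TO_NAMESPACE = {
    "P": "biological_process",
    "F": "molecular_function",
    "C": "cellular_component",
}


class GafParseError(Exception):
    """A GAF row that cannot be interpreted (reports the line number)."""


@dataclass
class AliasTable:
    """alias accession -> canonical accession map; identity fallback."""

    entries: dict[str, str] = field(default_factory=dict)

    def resolve(self, accession: str) -> str:
        return self.entries.get(accession, accession)


@dataclass
class AnnotationSet:
    """(canonical accession -> term ids) for one GO namespace."""

    namespace: str
    by_accession: dict[str, set[str]] = field(default_factory=dict)
    #: rows whose GO term was absent from the ontology graph
    skipped_unknown_terms: int = 0

    def add(self, accession: str, term: str) -> None:
        self.by_accession.setdefault(accession, set()).add(term)

    def get(self, accession: str) -> set[str]:
        return set(self.by_accession.get(accession, ()))

    def __len__(self) -> int:
        return len(self.by_accession)


def parse_alias_table(stream: IO[str] | str) -> AliasTable:
    """Read a two-column TSV (alias, canonical); the header is optional.

    A first line whose two fields look like column titles (contain no
    characters beyond letters/underscores and read ``alias``/``canonical``
    in any casing) is skipped.
    """
    if isinstance(stream, str):
        handle: IO[str] = open(stream, encoding="utf-8")
        close = True
    else:
        handle = stream
        close = False
    try:
        lines = handle.read().splitlines()
    finally:
        if close:
            handle.close()
    entries: dict[str, str] = {}
    for i, line in enumerate(lines):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise GafParseError(
                f"alias table line {i + 1}: expected 2 tab-separated columns"
            )
        alias, canonical = parts[0].strip(), parts[1].strip()
        if i == 0 and alias.lower() == "alias":
            continue
        entries[alias] = canonical
    return AliasTable(entries)


def parse_gaf(stream: IO[str] | str, graph: OntologyGraph) -> AnnotationSet:
    """Parse GAF 2.x text into an :class:`AnnotationSet`.

    Rows contribute only when their aspect (column 9) maps to the
    graph's namespace.  Rows whose qualifier (column 4) contains ``NOT``
    are negative statements and are skipped.  Terms not present in
    *graph* (obsolete, other namespace, or simply unknown) are skipped
    and counted on the returned set.

    Raises
    ------
    GafParseError
        For a non-comment row with fewer than 15 tab-separated columns.
    """
    if isinstance(stream, str):
        handle: IO[str] = open(stream, encoding="utf-8")
        close = True
    else:
        handle = stream
        close = False
    try:
        lines = handle.read().splitlines()
    finally:
        if close:
            handle.close()

    annotations = AnnotationSet(namespace=graph.namespace)
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) < 15:
            raise GafParseError(
                f"GAF line {lineno}: expected >=15 columns, got {len(cols)}"
            )
        qualifier = cols[3]
        if "NOT" in qualifier.split("|"):
            continue
        aspect = cols[8]
        if ASPECT_TO_NAMESPACE.get(aspect) != graph.namespace:
            continue
        accession, term = cols[1], cols[4]
        if term not in graph:
            annotations.skipped_unknown_terms += 1
            continue
        annotations.add(accession, term)
    if annotations.skipped_unknown_terms:
        logger.info(
            "parse_gaf: skipped %d rows whose GO term is absent from the %s graph",
            annotations.skipped_unknown_terms,
            graph.namespace or "(unrestricted)",
        )
    return annotations


def resolve(alias_table: AliasTable, accession: str) -> str:
    """Map *accession* through the alias table (identity when absent)."""
    return alias_table.resolve(accession)


def terms_for(
    annotations: AnnotationSet,
    alias_table: AliasTable,
    accession: str,
    namespace: str | None = None,
) -> set[str]:
    """Term set for *accession* after alias resolution.

    Returns the empty set for unannotated proteins; downstream filters
    treat an empty side as not evaluable.  *namespace*, when given, must
    match the annotation set's namespace (guards against wiring a
    molecular-function set into a cellular-function run).
    """
    if namespace is not None and annotations.namespace and namespace != annotations.namespace:
        raise ValueError(
            f"annotation set holds {annotations.namespace!r} terms, "
            f"but {namespace!r} was requested"
        )
    return annotations.get(alias_table.resolve(accession))
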