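"""Gene Ontology term graphs and common-ancestor distances.

GO structures each namespace (biological_process, molecular_function,
cellular_component) as a directed acyclic graph whose edges run from
child terms to parent terms.  The function filters need two quantities
from this graph: the minimal upward distance from a term to each of its
ancestors, and the pairwise distance between two terms defined as the
minimum, over all common ancestors ``c``, of ``dist(a, c) + dist(b, c)``
— the total number of edges connecting the pair through ``c``.  Two
identical terms are at distance 0 (each term is its own ancestor).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import networkx as nx
import obonet

__all__ = [
    "NO_COMMON_ANCESTOR",
    "NAMESPACES",
    "OntologyError",
    "OntologyParseError",
    "OntologyStructureError",
    "UnknownTermError",
    "TermRecord",
    "OntologyGraph",
    "parse_obo",
    "parse_edge_list",
    "ancestor_distances",
    "pair_distance",
]

#: Sentinel returned by :func:`pair_distance` when two terms share no
#: ancestor (possible when namespace restriction leaves multiple roots).
NO_COMMON_ANCESTOR = None

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")

DEFAULT_RELATIONS = frozenset({"is_a"})


class OntologyError(Exception):
    """Base class for ontology problems."""


class OntologyParseError(OntologyError):
    """Malformed OBO or edge-list input."""


class OntologyStructureError(OntologyError):
    """The parsed term graph violates a structural requirement (a cycle)."""


class UnknownTermError(KeyError, OntologyError):
    """A term id was looked up that is not in the graph."""


@dataclass(frozen=True)
class TermRecord:
    """One ontology term: id, human-readable name, namespace, parents."""

    id: str
    name: str = ""
    namespace: str = ""
    obsolete: bool = False
    parents: tuple[tuple[str, str], ...] = ()  # (parent id, relation label)


class OntologyGraph:
    """A single-namespace, acyclic child->parent term graph.

    Parameters
    ----------
    records
        Term id -> :class:`TermRecord`.
    edges
        Iterable of ``(child, parent)`` term-id pairs.  Both endpoints
        must be present in *records*.
    namespace
        The namespace this graph was restricted to (informational).
    """

    def __init__(
        self,
        records: Mapping[str, TermRecord],
        edges: Iterable[tuple[str, str]],
        namespace: str = "",
    ) -> None:
        self.records = dict(records)
        self.namespace = namespace
        g = nx.DiGraph()
        g.add_nodes_from(self.records)
        for child, parent in edges:
            if child not in self.records or parent not in self.records:
                missing = child if child not in self.records else parent
                raise OntologyStructureError(
                    f"edge ({child} -> {parent}) references unknown term {missing!r}"
                )
            g.add_edge(child, parent)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            pass
        else:
            path = " -> ".join(e[0] for e in cycle) + f" -> {cycle[-1][1]}"
            raise OntologyStructureError(f"term graph contains a cycle: {path}")
        self._graph = g
        self._distance_cache: dict[str, dict[str, int]] = {}

    # -- basic container protocol -------------------------------------
    def __contains__(self, term: str) -> bool:
        return term in self.records

    def __len__(self) -> int:
        return len(self.records)

    @property
    def terms(self) -> list[str]:
        return list(self.records)

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def parents(self, term: str) -> list[str]:
        self._check(term)
        return list(self._graph.successors(term))

    def children(self, term: str) -> list[str]:
        self._check(term)
        return list(self._graph.predecessors(term))

    def roots(self) -> list[str]:
        return [t for t in self._graph if self._graph.out_degree(t) == 0]

    def _check(self, term: str) -> None:
        if term not in self.records:
            raise UnknownTermError(f"term {term!r} not in ontology graph")

    def ancestor_distances(self, term: str) -> dict[str, int]:
        """Minimal upward edge counts from *term* to each ancestor.

        The term itself is included at distance 0.  Results are cached:
        the graph is immutable after construction.
        """
        self._check(term)
        cached = self._distance_cache.get(term)
        if cached is None:
            cached = nx.single_source_shortest_path_length(self._graph, term)
            self._distance_cache[term] = cached
        return dict(cached)

    def pair_distance(self, a: str, b: str) -> int | None:
        """Minimum total edge count from a common ancestor to *a* and *b*.

        Returns :data:`NO_COMMON_ANCESTOR` (``None``) when the ancestor
        sets are disjoint.  ``pair_distance(x, x) == 0`` for every term.
        """
        self._check(a)
        self._check(b)
        da = self.ancestor_distances(a)
        db = self.ancestor_distances(b)
        if len(db) < len(da):
            da, db = db, da
        best: int | None = None
        for term, d in da.items():
            other = db.get(term)
            if other is not None:
                total = d + other
                if best is None or total < best:
                    best = total
        return best


def _edges_from_record(rec: TermRecord, relations: frozenset[str]) -> list[tuple[str, str]]:
    return [(rec.id, parent) for parent, rel in rec.parents if rel in relations]


def parse_obo(
    stream: IO[str] | str,
    namespace: str | None = None,
    relations: Iterable[str] = DEFAULT_RELATIONS,
) -> OntologyGraph:
    """Parse OBO 1.2/1.4 text into an :class:`OntologyGraph`.

    Parameters
    ----------
    stream
        A path or an open text handle containing ``[Term]`` stanzas.
    namespace
        Keep only terms of this namespace (``None`` keeps everything;
        terms lacking a namespace tag are kept only when *namespace* is
        ``None``).
    relations
        Relation labels admitted as edges.  ``is_a`` only by default;
        add ``part_of`` to also follow part-of relationships.

    Obsolete terms are dropped before graph construction.  Edges whose
    parent falls outside the namespace restriction are dropped with the
    parent.  Acyclicity is verified and a cycle raises
    :class:`OntologyStructureError`.
    """
    relations = frozenset(relations)
    if isinstance(stream, str):
        handle: IO[str] = open(stream, encoding="utf-8")
        close = True
    else:
        handle = stream
        close = False
    try:
        try:
            # obonet keeps relationship edges keyed by their label and
            # drops obsolete stanzas; undeclared xrefs stay out of the way.
            multigraph = obonet.read_obo(handle, ignore_obsolete=True)
        except ValueError as exc:
            raise OntologyParseError(f"malformed OBO input: {exc}") from exc
    finally:
        if close:
            handle.close()

    records: dict[str, TermRecord] = {}
    for term, data in multigraph.nodes(data=True):
        ns = data.get("namespace", "")
        if namespace is not None and ns != namespace:
            continue
        parents: list[tuple[str, str]] = []
        for _, parent, rel in multigraph.out_edges(term, keys=True):
            parents.append((parent, rel))
        records[term] = TermRecord(
            id=term, name=data.get("name", ""), namespace=ns, parents=tuple(parents)
        )

    edges = []
    for rec in records.values():
        for child, parent in _edges_from_record(rec, relations):
            if parent in records:
                edges.append((child, parent))
    return OntologyGraph(records, edges, namespace=namespace or "")


def parse_edge_list(stream: IO[str] | str, namespace: str = "") -> OntologyGraph:
    """Parse a two-column child/parent TSV (one header line) into a graph.

    A fixture-friendly alternative to OBO: every term mentioned in
    either column becomes a node; every row an ``is_a`` edge.
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
    edges: list[tuple[str, str]] = []
    terms: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise OntologyParseError(
                f"line {lineno}: expected 2 tab-separated columns, got {len(parts)}"
            )
        child, parent = (p.strip() for p in parts)
        if not child or not parent:
            raise OntologyParseError(f"line {lineno}: empty term id")
        terms.update((child, parent))
        edges.append((child, parent))
    records = {
        t: TermRecord(id=t, namespace=namespace) for t in sorted(terms)
    }
    return OntologyGraph(records, edges, namespace=namespace)


def ancestor_distances(graph: OntologyGraph, term: str) -> dict[str, int]:
    """Minimal upward distances from *term*; the term itself maps to 0."""
    return graph.ancestor_distances(term)


def pair_distance(graph: OntologyGraph, a: str, b: str) -> int | None:
    """Minimal common-ancestor total distance between terms *a* and *b*."""
    return graph.pair_distance(a, b)
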