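"""Ontology terms, is_a hierarchy and CURIE/IRI handling.

The ontology is loaded from two flat TSV tables — a term table
(``curie  label  parents  category``, parents pipe-separated) and an optional
relation table (``curie  label  domain  range``) — rather than from OWL: the
tool needs the class hierarchy, labels and relation signatures, not
description-logic semantics.

Transitive is_a closure over the acyclic hierarchy provides the broader
(ancestor) and narrower (descendant) term sets used to expand MeSH filters,
and the label index backs autocomplete-style partial term lookup.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx

from .vocab import OBO_BASE

CATEGORIES = ("miRNA", "gene", "MeSH", "class")

_CURIE_RE = re.compile(r"^([A-Z][A-Z0-9]*)_(\d+)$")


class OntologyError(ValueError):
    """Raised for malformed ontology inputs (duplicates, cycles, bad ids)."""


def is_valid_curie(curie: str) -> bool:
    return bool(_CURIE_RE.match(curie))


def curie_to_iri(curie: str) -> str:
    """Expand ``PREFIX_NNNNNNN`` under the OBO PURL base."""
    if not is_valid_curie(curie):
        raise OntologyError(f"malformed CURIE: {curie!r}")
    return OBO_BASE + curie


def iri_to_curie(iri: str) -> str:
    """Inverse of :func:`curie_to_iri`."""
    if not iri.startswith(OBO_BASE):
        raise OntologyError(f"IRI not under the OBO PURL base: {iri!r}")
    curie = iri[len(OBO_BASE):]
    if not is_valid_curie(curie):
        raise OntologyError(f"IRI local part is not a CURIE: {iri!r}")
    return curie


@dataclass(frozen=True)
class Term:
    id: str
    label: str
    parents: frozenset[str] = frozenset()
    category: str = "class"


@dataclass(frozen=True)
class RelationDef:
    id: str
    label: str
    domain: str
    range: str


@dataclass
class OntologyGraph:
    """Indexed term set with an acyclic is_a hierarchy."""

    terms: dict[str, Term] = field(default_factory=dict)
    relations: dict[str, RelationDef] = field(default_factory=dict)
    #: (child, missing-parent) pairs found at load time; kept, not dropped
    dangling_parents: list[tuple[str, str]] = field(default_factory=list)
    _dag: nx.DiGraph = field(default_factory=nx.DiGraph, repr=False)
    _label_index: dict[tuple[str, str], str] = field(default_factory=dict, repr=False)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def term(self, term_id: str) -> Term:
        try:
            return self.terms[term_id]
        except KeyError:
            raise OntologyError(f"unknown term: {term_id}") from None

    def label_to_id(self, label: str, category: str) -> Optional[str]:
        """Exact (case-insensitive) label lookup within a category."""
        return self._label_index.get((category, label.casefold()))

    def ancestors(self, term_id: str) -> set[str]:
        """All broader terms: the transitive is_a closure, excluding the term."""
        self.term(term_id)
        return set(nx.descendants(self._dag, term_id))  # edges point child->parent

    def descendants(self, term_id: str) -> set[str]:
        """All narrower terms: reverse transitive closure, excluding the term."""
        self.term(term_id)
        return set(nx.ancestors(self._dag, term_id))

    def find_terms(self, partial: str, category: Optional[str] = None) -> list[str]:
        """Case-insensitive substring search over labels.

        An empty ``partial`` returns every label of the category.  Results
        are sorted lexicographically; no match yields an empty list.
        """
        needle = partial.casefold()
        labels = [
            t.label
            for t in self.terms.values()
            if (category is None or t.category == category)
            and needle in t.label.casefold()
        ]
        return sorted(labels)

    def category_terms(self, category: str) -> list[Term]:
        return sorted(
            (t for t in self.terms.values() if t.category == category),
            key=lambda t: t.id,
        )


def _add_term(graph: OntologyGraph, term: Term) -> None:
    if not is_valid_curie(term.id):
        raise OntologyError(f"malformed CURIE: {term.id!r}")
    if term.id in graph.terms:
        raise OntologyError(f"duplicate CURIE: {term.id}")
    if not term.label:
        raise OntologyError(f"term {term.id} has an empty label")
    if term.category not in CATEGORIES:
        raise OntologyError(f"unknown category {term.category!r} for {term.id}")
    key = (term.category, term.label.casefold())
    if key in graph._label_index:
        raise OntologyError(
            f"label collision in category {term.category!r}: "
            f"{term.label!r} used by {graph._label_index[key]} and {term.id}"
        )
    graph.terms[term.id] = term
    graph._label_index[key] = term.id
    graph._dag.add_node(term.id)


def build_ontology(
    terms: Iterable[Term], relations: Iterable[RelationDef] = ()
) -> OntologyGraph:
    """Index terms and relations, validating uniqueness and acyclicity."""
    graph = OntologyGraph()
    for term in terms:
        _add_term(graph, term)
    for term in graph.terms.values():
        for parent in sorted(term.parents):
            if parent in graph.terms:
                graph._dag.add_edge(term.id, parent)
            else:
                graph.dangling_parents.append((term.id, parent))
    if not nx.is_directed_acyclic_graph(graph._dag):
        cycle = nx.find_cycle(graph._dag)
        nodes = sorted({edge[0] for edge in cycle})
        raise OntologyError(f"cyclic is_a hierarchy through: {', '.join(nodes)}")
    for rel in relations:
        if rel.id in graph.relations:
            raise OntologyError(f"duplicate relation CURIE: {rel.id}")
        for endpoint in (rel.domain, rel.range):
            if endpoint not in graph.terms:
                raise OntologyError(
                    f"relation {rel.id} references unknown term {endpoint}"
                )
        graph.relations[rel.id] = rel
    return graph


def _read_tsv(path: Path, expected_header: list[str]) -> list[dict[str, str]]:
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames != expected_header:
            raise OntologyError(
                f"{path}: expected header {expected_header}, got {reader.fieldnames}"
            )
        return [row for row in reader if any((v or "").strip() for v in row.values())]


def load_ontology(term_file, relation_file=None) -> OntologyGraph:
    """Load an ontology from TSV tables (see module docstring for layout)."""
    term_rows = _read_tsv(Path(term_file), ["curie", "label", "parents", "category"])
    terms = [
        Term(
            id=row["curie"].strip(),
            label=row["label"].strip(),
            parents=frozenset(
                p.strip() for p in (row["parents"] or "").split("|") if p.strip()
            ),
            category=row["category"].strip(),
        )
        for row in term_rows
    ]
    relations: list[RelationDef] = []
    if relation_file is not None:
        rel_rows = _read_tsv(Path(relation_file), ["curie", "label", "domain", "range"])
        relations = [
            RelationDef(
                id=row["curie"].strip(),
                label=row["label"].strip(),
                domain=row["domain"].strip(),
                range=row["range"].strip(),
            )
            for row in rel_rows
        ]
    return build_ontology(terms, relations)


def save_ontology_tables(
    terms: Iterable[Term],
    relations: Iterable[RelationDef],
    term_file,
    relation_file,
) -> None:
    """Write the TSV tables that :func:`load_ontology` reads."""
    with open(term_file, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["curie", "label", "parents", "category"])
        for t in terms:
            writer.writerow([t.id, t.label, "|".join(sorted(t.parents)), t.category])
    with open(relation_file, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["curie", "label", "domain", "range"])
        for r in relations:
            writer.writerow([r.id, r.label, r.domain, r.range])
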