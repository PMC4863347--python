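"""RDF triples, typed literals, instance minting and Turtle I/O.

The in-memory representation is deliberately small: a triple is a frozen
``(subject, predicate, object)`` record where subject and predicate are IRI
strings and the object is either an IRI string or a :class:`Literal` carrying
an explicit XSD datatype (integer, decimal or string).

Serialization is a deterministic Turtle emitter (triples sorted by subject,
predicate, object; fixed prefix block) so that re-running a pipeline on
identical input produces byte-identical output.  Parsing goes through rdflib
and therefore accepts any valid Turtle document whose content stays within
the supported literal datatypes and contains no blank nodes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import Decimal, InvalidOperation
from typing import Iterable, Mapping, Union

import rdflib
from rdflib.namespace import XSD

from .vocab import (
    DCTERMS_NS,
    OBO_BASE,
    RDF_NS,
    RDFS_NS,
    XSD_DECIMAL,
    XSD_INTEGER,
    XSD_NS,
    XSD_STRING,
)


class TurtleError(ValueError):
    """Raised for unsupported datatypes or malformed Turtle."""


_SUPPORTED_DATATYPES = (XSD_INTEGER, XSD_DECIMAL, XSD_STRING)


def _decimal_lexical(value: Decimal) -> str:
    # avoid exponent notation; Turtle xsd:decimal has no 'E' form
    text = format(value, "f")
    return text


@dataclass(frozen=True)
class Literal:
    """A typed RDF literal held in canonical lexical form."""

    lexical: str
    datatype: str = XSD_STRING

    def __post_init__(self) -> None:
        if self.datatype not in _SUPPORTED_DATATYPES:
            raise TurtleError(f"unsupported literal datatype: {self.datatype}")

    @classmethod
    def integer(cls, value: int) -> "Literal":
        return cls(str(int(value)), XSD_INTEGER)

    @classmethod
    def decimal(cls, value) -> "Literal":
        return cls(_decimal_lexical(Decimal(str(value))), XSD_DECIMAL)

    @classmethod
    def string(cls, value: str) -> "Literal":
        return cls(str(value), XSD_STRING)

    @property
    def value(self) -> Union[int, Decimal, str]:
        """The literal as a native Python value."""
        if self.datatype == XSD_INTEGER:
            return int(self.lexical)
        if self.datatype == XSD_DECIMAL:
            return Decimal(self.lexical)
        return self.lexical


Node = Union[str, Literal]


@dataclass(frozen=True)
class Triple:
    subject: str
    predicate: str
    object: Node


def node_sort_key(node: Node):
    if isinstance(node, Literal):
        return (1, node.datatype, node.lexical)
    return (0, "", node)


def triple_sort_key(t: Triple):
    return (t.subject, t.predicate) + node_sort_key(t.object)


class InstanceMinter:
    """Mints fresh instance CURIEs from a reserved 7-digit numeric block.

    Ids are strictly increasing and deterministic given call order, so a
    pipeline re-run over identical input reproduces the same graph byte for
    byte.
    """

    def __init__(self, prefix: str = "OMIT", start: int = 900000):
        if not (0 <= start <= 9_999_999):
            raise ValueError("minter start must fit in 7 digits")
        self.prefix = prefix
        self._next = start

    def mint(self) -> str:
        if self._next > 9_999_999:
            raise OverflowError("instance id range exhausted")
        curie = f"{self.prefix}_{self._next:07d}"
        self._next += 1
        return curie

    @property
    def next_value(self) -> int:
        return self._next


DEFAULT_PREFIXES: Mapping[str, str] = {
    "obo": OBO_BASE,
    "rdf": RDF_NS,
    "rdfs": RDFS_NS,
    "xsd": XSD_NS,
    "dcterms": DCTERMS_NS,
}

_PN_LOCAL = re.compile(r"^[A-Za-z_][A-Za-z0-9_\-]*$")
_STRING_ESCAPES = {
    "\\": "\\\\",
    '"': '\\"',
    "\n": "\\n",
    "\r": "\\r",
    "\t": "\\t",
}


def _escape(text: str) -> str:
    return "".join(_STRING_ESCAPES.get(ch, ch) for ch in text)


def _qname(iri: str, prefixes: Mapping[str, str]) -> str:
    for prefix, ns in prefixes.items():
        if iri.startswith(ns):
            local = iri[len(ns):]
            if _PN_LOCAL.match(local):
                return f"{prefix}:{local}"
    return f"<{iri}>"


def _render_node(node: Node, prefixes: Mapping[str, str]) -> str:
    if isinstance(node, Literal):
        if node.datatype not in _SUPPORTED_DATATYPES:  # defensive
            raise TurtleError(f"unsupported literal datatype: {node.datatype}")
        return f'"{_escape(node.lexical)}"^^{_qname(node.datatype, prefixes)}'
    return _qname(node, prefixes)


def serialize_turtle(
    triples: Iterable[Triple], prefixes: Mapping[str, str] | None = None
) -> str:
    """Serialize triples as deterministic RDF 1.1 Turtle (UTF-8, LF)."""
    prefixes = dict(DEFAULT_PREFIXES if prefixes is None else prefixes)
    lines = [f"@prefix {p}: <{ns}> ." for p, ns in sorted(prefixes.items())]
    lines.append("")
    for t in sorted(set(triples), key=triple_sort_key):
        s = _qname(t.subject, prefixes)
        p = _qname(t.predicate, prefixes)
        o = _render_node(t.object, prefixes)
        lines.append(f"{s} {p} {o} .")
    return "\n".join(lines) + "\n"


def _from_rdflib(node) -> Node:
    if isinstance(node, rdflib.URIRef):
        return str(node)
    if isinstance(node, rdflib.Literal):
        dt = node.datatype
        if dt is None or dt == XSD.string:
            return Literal.string(str(node))
        if dt == XSD.integer:
            return Literal.integer(int(node))
        if dt in (XSD.decimal, XSD.double, XSD.float):
            return Literal(_decimal_lexical(Decimal(str(node))), XSD_DECIMAL)
        raise TurtleError(f"unsupported literal datatype: {dt}")
    raise TurtleError(f"unsupported node (blank nodes not allowed): {node!r}")


def parse_turtle(text: str) -> list[Triple]:
    """Parse a Turtle document into a sorted triple list.

    Raises :class:`TurtleError` with the offending line number on syntax
    errors, and for blank nodes or datatypes outside the supported subset.
    """
    graph = rdflib.Graph()
    try:
        graph.parse(data=text, format="turtle")
    except Exception as exc:  # rdflib raises plugin-specific classes
        lines = getattr(exc, "lines", None)  # newlines before the error
        detail = f" at line {lines + 1}" if isinstance(lines, int) else ""
        raise TurtleError(f"Turtle syntax error{detail}: {exc}") from exc
    out = []
    for s, p, o in graph:
        if not isinstance(s, rdflib.URIRef) or not isinstance(p, rdflib.URIRef):
            raise TurtleError("blank-node subjects are not supported")
        out.append(Triple(str(s), str(p), _from_rdflib(o)))
    return sorted(out, key=triple_sort_key)


def parse_score(text: str) -> Decimal:
    """Parse a prediction score field; raises ValueError when not numeric."""
    try:
        return Decimal(str(text).strip())
    except InvalidOperation as exc:
        raise ValueError(f"unparseable score: {text!r}") from exc
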