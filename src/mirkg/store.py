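"""In-memory indexed triple store with conjunctive graph-pattern matching.

This is the desk-scale stand-in for a SPARQL endpoint: queries are
programmatic lists of triple patterns (constants or named variables in each
position) evaluated conjunctively with set semantics, plus optional
substring/regex filters on bound variables.  Join order is an internal
choice and never affects the solution set; output order is deterministic
(sorted by the variables' values).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

from .triples import Literal, Node, Triple, node_sort_key, triple_sort_key


class QueryError(ValueError):
    pass


@dataclass(frozen=True)
class Var:
    """A named query variable; names share one scope within a query."""

    name: str


PatternNode = Union[Var, str, Literal]


@dataclass(frozen=True)
class TriplePattern:
    subject: PatternNode
    predicate: PatternNode
    object: PatternNode

    def variables(self) -> set[str]:
        return {n.name for n in (self.subject, self.predicate, self.object)
                if isinstance(n, Var)}


@dataclass(frozen=True)
class Filter:
    """Substring (default) or regex restriction on a variable's string form.

    IRIs filter on the full IRI; literals on their lexical form.
    """

    var: str
    pattern: str
    regex: bool = False
    case_insensitive: bool = True

    def accepts(self, value: Node) -> bool:
        text = value.lexical if isinstance(value, Literal) else value
        if self.regex:
            flags = re.IGNORECASE if self.case_insensitive else 0
            return re.search(self.pattern, text, flags) is not None
        if self.case_insensitive:
            return self.pattern.casefold() in text.casefold()
        return self.pattern in text


@dataclass
class BindingSet:
    """Distinct solutions, each binding exactly the query's variables."""

    variables: tuple[str, ...]
    solutions: list[dict[str, Node]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.solutions)

    def __iter__(self):
        return iter(self.solutions)

    def column(self, var: str) -> list[Node]:
        return [sol[var] for sol in self.solutions]

    def to_rows(self) -> list[dict]:
        """JSON-ready rows: IRIs as strings, literals as native values."""
        def plain(node: Node):
            if isinstance(node, Literal):
                v = node.value
                return float(v) if hasattr(v, "quantize") else v
            return node

        return [{v: plain(sol[v]) for v in self.variables} for sol in self.solutions]


class TripleStore:
    """Deduplicated triple set with subject/predicate/object posting lists."""

    def __init__(self, triples: Iterable[Triple] = ()):
        self._triples: set[Triple] = set()
        self._by_s: dict[str, set[Triple]] = {}
        self._by_p: dict[str, set[Triple]] = {}
        self._by_o: dict[Node, set[Triple]] = {}
        self.add_all(triples)

    def add(self, triple: Triple) -> None:
        if triple in self._triples:
            return
        self._triples.add(triple)
        self._by_s.setdefault(triple.subject, set()).add(triple)
        self._by_p.setdefault(triple.predicate, set()).add(triple)
        self._by_o.setdefault(triple.object, set()).add(triple)

    def add_all(self, triples: Iterable[Triple]) -> None:
        for t in triples:
            self.add(t)

    def __len__(self) -> int:
        return len(self._triples)

    def __contains__(self, triple: Triple) -> bool:
        return triple in self._triples

    def triples(self) -> list[Triple]:
        return sorted(self._triples, key=triple_sort_key)

    def candidates(
        self,
        subject: Optional[Node] = None,
        predicate: Optional[Node] = None,
        object: Optional[Node] = None,
    ) -> set[Triple]:
        """Triples matching the bound (non-None) positions, via the smallest
        applicable posting list."""
        lists = []
        if subject is not None:
            lists.append(self._by_s.get(subject, set()))
        if predicate is not None:
            lists.append(self._by_p.get(predicate, set()))
        if object is not None:
            lists.append(self._by_o.get(object, set()))
        if not lists:
            return set(self._triples)
        smallest = min(lists, key=len)
        out = smallest
        for other in lists:
            if other is not smallest:
                out = out & other
        return set(out)


def _resolve(node: PatternNode, binding: Mapping[str, Node]) -> Optional[Node]:
    if isinstance(node, Var):
        return binding.get(node.name)
    return node


def _extend(
    pattern: TriplePattern, triple: Triple, binding: dict[str, Node]
) -> Optional[dict[str, Node]]:
    out = dict(binding)
    for pnode, tnode in (
        (pattern.subject, triple.subject),
        (pattern.predicate, triple.predicate),
        (pattern.object, triple.object),
    ):
        if isinstance(pnode, Var):
            bound = out.get(pnode.name)
            if bound is None:
                out[pnode.name] = tnode
            elif bound != tnode:
                return None
        elif pnode != tnode:
            return None
    return out


def match(
    store: TripleStore,
    patterns: Sequence[TriplePattern],
    filters: Sequence[Filter] = (),
) -> BindingSet:
    """Evaluate a conjunctive basic graph pattern with set semantics.

    Patterns are joined left to right with index-backed candidate lookup;
    filters apply to the final solutions (filtering commutes with joining
    because filters only constrain, never bind).  Filtering on a variable
    the query never binds is an error.
    """
    if not patterns:
        raise QueryError("query needs at least one pattern")
    qvars = set()
    for pattern in patterns:
        qvars |= pattern.variables()
    for f in filters:
        if f.var not in qvars:
            raise QueryError(f"filter on unbound variable ?{f.var}")

    solutions: list[dict[str, Node]] = [{}]
    for pattern in patterns:
        extended: list[dict[str, Node]] = []
        for binding in solutions:
            cands = store.candidates(
                _resolve(pattern.subject, binding),
                _resolve(pattern.predicate, binding),
                _resolve(pattern.object, binding),
            )
            for triple in cands:
                new = _extend(pattern, triple, binding)
                if new is not None:
                    extended.append(new)
        solutions = extended
        if not solutions:
            break

    kept = [
        sol
        for sol in solutions
        if all(f.accepts(sol[f.var]) for f in filters)
    ]
    ordered_vars = tuple(sorted(qvars))
    unique = {tuple(sol[v] for v in ordered_vars) for sol in kept}
    ordered = sorted(unique, key=lambda row: tuple(node_sort_key(n) for n in row))
    return BindingSet(
        variables=ordered_vars,
        solutions=[dict(zip(ordered_vars, row)) for row in ordered],
    )
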