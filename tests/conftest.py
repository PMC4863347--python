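"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's own code paths: closure
is computed by exhaustive path enumeration, and graph-pattern matching by
enumerating every assignment of store triples to patterns.
"""

from __future__ import annotations

import itertools
import random

import pytest
from hypothesis import settings

from mirkg.ontology import Term, build_ontology
from mirkg.store import TriplePattern, Var
from mirkg.triples import Literal, Triple, node_sort_key

settings.register_profile("suite", derandomize=True, max_examples=40, deadline=None)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# ontology helpers
# ---------------------------------------------------------------------------

def make_chain():
    """C is_a B is_a A."""
    return build_ontology(
        [
            Term("EX_0000001", "A", frozenset(), "MeSH"),
            Term("EX_0000002", "B", frozenset(["EX_0000001"]), "MeSH"),
            Term("EX_0000003", "C", frozenset(["EX_0000002"]), "MeSH"),
        ]
    )


def random_dag_terms(n_terms: int, seed: int, category: str = "MeSH"):
    """A random DAG on n_terms nodes: each node may take parents among
    earlier nodes only, which guarantees acyclicity."""
    rng = random.Random(seed)
    terms = []
    ids = [f"EX_{i + 1:07d}" for i in range(n_terms)]
    for i, term_id in enumerate(ids):
        k = rng.randint(0, min(2, i))
        parents = frozenset(rng.sample(ids[:i], k)) if k else frozenset()
        terms.append(Term(term_id, f"term {i}", parents, category))
    return terms


def brute_ancestors(terms, term_id: str) -> set[str]:
    """Reachability by explicit path enumeration over is_a edges."""
    parents = {t.id: set(t.parents) for t in terms}
    found: set[str] = set()
    stack = [[term_id]]
    while stack:
        path = stack.pop()
        for parent in parents.get(path[-1], ()):
            if parent in parents and parent not in path:
                found.add(parent)
                stack.append(path + [parent])
    return found


def brute_descendants(terms, term_id: str) -> set[str]:
    return {t.id for t in terms if term_id in brute_ancestors(terms, t.id)}


# ---------------------------------------------------------------------------
# BGP oracle
# ---------------------------------------------------------------------------

def _unify(pattern: TriplePattern, triple: Triple, binding: dict):
    out = dict(binding)
    for pnode, tnode in (
        (pattern.subject, triple.subject),
        (pattern.predicate, triple.predicate),
        (pattern.object, triple.object),
    ):
        if isinstance(pnode, Var):
            if pnode.name in out:
                if out[pnode.name] != tnode:
                    return None
            else:
                out[pnode.name] = tnode
        elif pnode != tnode:
            return None
    return out


def brute_match(triples, patterns, filters=()):
    """Enumerate every assignment of store triples to patterns; returns the
    distinct solutions as a set of (var, value) frozensets."""
    triples = list(triples)
    solutions = set()
    for combo in itertools.product(triples, repeat=len(patterns)):
        binding: dict | None = {}
        for pattern, triple in zip(patterns, combo):
            binding = _unify(pattern, triple, binding)
            if binding is None:
                break
        if binding is None:
            continue
        if all(f.accepts(binding[f.var]) for f in filters):
            solutions.add(frozenset(binding.items()))
    return solutions


def random_store_triples(n: int, seed: int) -> list[Triple]:
    rng = random.Random(seed)
    subjects = [f"http://example.org/s{i}" for i in range(max(2, n // 6))]
    predicates = [f"http://example.org/p{i}" for i in range(3)]
    objects: list = subjects + [Literal.integer(i) for i in range(4)]
    triples = set()
    while len(triples) < n:
        triples.add(
            Triple(rng.choice(subjects), rng.choice(predicates), rng.choice(objects))
        )
    return sorted(triples, key=lambda t: (t.subject, t.predicate, node_sort_key(t.object)))


# ---------------------------------------------------------------------------
# shared fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def chain_graph():
    return make_chain()
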