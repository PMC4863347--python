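"""Integrated search over the miRNA-target knowledge graph.

Given per-source prediction graphs, evidence records and the ontology, a
search for one miRNA returns a result table of candidate target genes:

* the candidate set is the union (``any``), intersection (``all``) or a
  single source's set (``specific``) of per-database predictions — a
  configured source with no predictions for the miRNA makes the
  intersection empty, which is exactly how absence of coverage should read;
* publications attach to a row only when linked to both that gene and the
  miRNA, and (when a MeSH filter is set) when they carry a term from the
  MeSH expansion — the exact term, its broader (ancestor) terms, its
  narrower (descendant) terms, or all of these;
* rows sort descending by the chosen database's score (rows lacking that
  score trail, ties break on gene symbol), then paginate.

The evaluation helpers compute the publication-reduction percentage of the
MeSH filter and precision/recall of a returned publication set against a
supplied gold standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence, Union

from . import vocab
from .annotate import (
    SOURCE_CONFIGS,
    GoAnnotation,
    Publication,
    SourceConfig,
)
from .ontology import OntologyGraph, curie_to_iri, iri_to_curie, is_valid_curie
from .store import TriplePattern, TripleStore, Var, match
from .triples import Literal


class SearchError(ValueError):
    pass


MESH_MODES = ("exact", "broader", "narrower", "exact+broader+narrower")
DB_FILTERS = ("any", "all", "specific")
EVIDENCE_FILTERS = ("with_publications", "without_publications", "both")


@dataclass(frozen=True)
class SearchRequest:
    mirna: str                       # miRNA name or CURIE
    mesh_term: Optional[str] = None  # CURIE of the MeSH filter term
    mesh_mode: str = "exact"
    db_filter: str = "any"
    specific_source: Optional[str] = None
    sort_db: Optional[str] = None
    page: int = 1
    rows_per_page: Optional[int] = None
    evidence_filter: str = "both"

    def __post_init__(self):
        if self.mesh_mode not in MESH_MODES:
            raise SearchError(f"unknown mesh_mode: {self.mesh_mode!r}")
        if self.db_filter not in DB_FILTERS:
            raise SearchError(f"unknown db_filter: {self.db_filter!r}")
        if self.db_filter == "specific" and not self.specific_source:
            raise SearchError("db_filter='specific' needs specific_source")
        if self.evidence_filter not in EVIDENCE_FILTERS:
            raise SearchError(f"unknown evidence_filter: {self.evidence_filter!r}")
        if self.page < 1:
            raise SearchError("page must be >= 1")
        if self.rows_per_page is not None and self.rows_per_page < 1:
            raise SearchError("rows_per_page must be >= 1")


@dataclass
class ResultRow:
    gene_id: str
    gene_symbol: str
    predicted_by: set[str] = field(default_factory=set)
    scores: dict[str, Decimal] = field(default_factory=dict)
    publications: set[int] = field(default_factory=set)
    go_annotations: set[GoAnnotation] = field(default_factory=set)


@dataclass
class ResultTable:
    rows: list[ResultRow] = field(default_factory=list)
    total_distinct_targets: int = 0
    page: int = 1
    rows_per_page: Optional[int] = None
    warning: Optional[str] = None

    def to_json_rows(self) -> list[dict]:
        """GUI-shaped rows: target, predicted-by, per-source scores,
        publications, GO annotations."""
        out = []
        for row in self.rows:
            out.append(
                {
                    "candidate_target": row.gene_symbol,
                    "gene_id": row.gene_id,
                    "predicted_by": sorted(row.predicted_by),
                    "scores": {s: float(v) for s, v in sorted(row.scores.items())},
                    "publications": sorted(row.publications),
                    "go_annotations": [
                        {"go_term": g.go_term, "go_ref": g.go_ref}
                        for g in sorted(
                            row.go_annotations, key=lambda g: (g.go_term, g.go_ref)
                        )
                    ],
                }
            )
        return out


@dataclass
class EvidenceSet:
    publications: list[Publication] = field(default_factory=list)
    go_annotations: list[GoAnnotation] = field(default_factory=list)


# ---------------------------------------------------------------------------
# MeSH expansion
# ---------------------------------------------------------------------------

def mesh_expand(graph: OntologyGraph, term: str, mode: str = "exact") -> set[str]:
    """Expand a MeSH term per the requested mode (term always included)."""
    if mode not in MESH_MODES:
        raise SearchError(f"unknown mesh_mode: {mode!r}")
    graph.term(term)  # raises OntologyError on unknown terms
    out = {term}
    if mode in ("broader", "exact+broader+narrower"):
        out |= graph.ancestors(term)
    if mode in ("narrower", "exact+broader+narrower"):
        out |= graph.descendants(term)
    return out


# ---------------------------------------------------------------------------
# store extraction
# ---------------------------------------------------------------------------

def extract_predictions(
    store: TripleStore, cfg: SourceConfig, mirna_iri: str
) -> dict[str, Decimal]:
    """Gene CURIE -> score for one source's predictions of one miRNA."""
    inst, gene, score = Var("inst"), Var("gene"), Var("score")
    patterns = [
        TriplePattern(inst, vocab.RDF_TYPE, curie_to_iri(cfg.record_class)),
        TriplePattern(inst, curie_to_iri(cfg.participant_predicate), mirna_iri),
        TriplePattern(inst, curie_to_iri(cfg.participant_predicate), gene),
        TriplePattern(inst, curie_to_iri(cfg.score_predicate), score),
    ]
    out: dict[str, Decimal] = {}
    for sol in match(store, patterns):
        gene_node = sol["gene"]
        if gene_node == mirna_iri or isinstance(gene_node, Literal):
            continue  # the participant pattern also rebinds the miRNA itself
        value = sol["score"].value
        out[iri_to_curie(gene_node)] = Decimal(value) if isinstance(value, int) else value
    return out


def extract_gene_info(store: TripleStore) -> dict[str, tuple[str, str]]:
    """Gene CURIE -> (gene id, symbol) for every declared target gene."""
    gene, label = Var("gene"), Var("label")
    sub = match(
        store,
        [
            TriplePattern(
                gene, vocab.RDFS_SUBCLASSOF, curie_to_iri(vocab.MIRNA_TARGET_GENE)
            ),
            TriplePattern(gene, vocab.RDFS_LABEL, label),
        ],
    )
    ids = {
        sol["gene"]: sol["ident"].lexical
        for sol in match(
            store,
            [TriplePattern(gene, vocab.DCTERMS_IDENTIFIER, Var("ident"))],
        )
    }
    out: dict[str, tuple[str, str]] = {}
    for sol in sub:
        gene_iri = sol["gene"]
        curie = iri_to_curie(gene_iri)
        out[curie] = (ids.get(gene_iri, curie), sol["label"].lexical)
    return out


# ---------------------------------------------------------------------------
# search proper
# ---------------------------------------------------------------------------

def _resolve_mirna(graph: OntologyGraph, mirna: str) -> Optional[str]:
    if is_valid_curie(mirna) and mirna in graph:
        return mirna
    return graph.label_to_id(mirna, "miRNA")


def _store_for(stores, source: str) -> TripleStore:
    if isinstance(stores, TripleStore):
        return stores
    try:
        return stores[source]
    except KeyError:
        raise SearchError(f"no store configured for source {source!r}") from None


def search(
    stores: Union[TripleStore, Mapping[str, TripleStore]],
    evidence: EvidenceSet,
    graph: OntologyGraph,
    req: SearchRequest,
    sources: Optional[Sequence[SourceConfig]] = None,
) -> ResultTable:
    """Run one integrated search; see the module docstring for semantics."""
    configs = list(sources) if sources is not None else list(SOURCE_CONFIGS.values())
    if req.db_filter == "specific" and req.specific_source not in {
        c.name for c in configs
    }:
        raise SearchError(f"unconfigured source: {req.specific_source!r}")

    mirna_curie = _resolve_mirna(graph, req.mirna)
    if mirna_curie is None:
        return ResultTable(warning=f"unknown miRNA: {req.mirna!r}")
    mirna_iri = curie_to_iri(mirna_curie)

    mesh_set: Optional[set[str]] = None
    if req.mesh_term is not None:
        mesh_set = mesh_expand(graph, req.mesh_term, req.mesh_mode)

    predictions = {
        cfg.name: extract_predictions(_store_for(stores, cfg.name), cfg, mirna_iri)
        for cfg in configs
    }
    gene_info: dict[str, tuple[str, str]] = {}
    seen_stores = []
    for cfg in configs:
        st = _store_for(stores, cfg.name)
        if any(st is s for s in seen_stores):
            continue
        seen_stores.append(st)
        gene_info.update(extract_gene_info(st))

    if req.db_filter == "any":
        candidates: set[str] = set()
        for preds in predictions.values():
            candidates |= preds.keys()
    elif req.db_filter == "all":
        candidates = set.intersection(
            *(set(preds.keys()) for preds in predictions.values())
        ) if predictions else set()
    else:
        candidates = set(predictions[req.specific_source].keys())

    go_by_gene: dict[str, set[GoAnnotation]] = {}
    for go in evidence.go_annotations:
        go_by_gene.setdefault(go.gene_id, set()).add(go)

    rows: list[ResultRow] = []
    for curie in candidates:
        gene_id, symbol = gene_info.get(curie, (curie, curie))
        predicted_by = {s for s, preds in predictions.items() if curie in preds}
        scores = {s: predictions[s][curie] for s in predicted_by}
        pmids = {
            pub.pmid
            for pub in evidence.publications
            if gene_id in pub.gene_ids
            and mirna_curie in pub.mirna_ids
            and (mesh_set is None or pub.mesh_terms & mesh_set)
        }
        rows.append(
            ResultRow(
                gene_id=gene_id,
                gene_symbol=symbol,
                predicted_by=predicted_by,
                scores=scores,
                publications=pmids,
                go_annotations=go_by_gene.get(gene_id, set()),
            )
        )

    if req.evidence_filter == "with_publications":
        rows = [r for r in rows if r.publications]
    elif req.evidence_filter == "without_publications":
        rows = [r for r in rows if not r.publications]

    rows.sort(key=lambda r: (r.gene_symbol, r.gene_id))
    table = ResultTable(rows=rows, total_distinct_targets=len(rows))
    if req.sort_db is not None:
        table = sort_rows(table, req.sort_db)
    if req.rows_per_page is not None:
        table = paginate(table, req.page, req.rows_per_page)
    return table


def sort_rows(table: ResultTable, sort_db: str) -> ResultTable:
    """Descending by the chosen database's score; scoreless rows trail;
    ties and trailing rows order by gene symbol ascending."""
    def key(row: ResultRow):
        score = row.scores.get(sort_db)
        if score is None:
            return (1, Decimal(0), row.gene_symbol, row.gene_id)
        return (0, -score, row.gene_symbol, row.gene_id)

    return replace(table, rows=sorted(table.rows, key=key))


def paginate(table: ResultTable, page: int, rows_per_page: int) -> ResultTable:
    """Slice out one page; a page beyond the end is empty, not an error."""
    if page < 1 or rows_per_page < 1:
        raise SearchError("page and rows_per_page must be >= 1")
    start = (page - 1) * rows_per_page
    return replace(
        table,
        rows=table.rows[start : start + rows_per_page],
        page=page,
        rows_per_page=rows_per_page,
    )


# ---------------------------------------------------------------------------
# evaluation statistics
# ---------------------------------------------------------------------------

def percent_reduction(before: int, after: int) -> int:
    """Publication-count reduction as a whole percentage.

    Rounds to the nearest integer, halves away from zero.
    """
    if before <= 0:
        raise SearchError("before must be > 0")
    if after < 0 or after > before:
        raise SearchError("need before >= after >= 0")
    fraction = Decimal(100) * (Decimal(before) - Decimal(after)) / Decimal(before)
    return int(fraction.quantize(Decimal(1), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PrecisionRecall:
    precision: Optional[float]  # None when no publications were returned
    recall: Optional[float]     # None when the gold set is empty


def precision_recall(
    returned: Sequence[Publication],
    term_set: set[str],
    gold: set[int],
) -> PrecisionRecall:
    """Precision of a MeSH-filtered publication set, and recall against a
    supplied gold-standard PMID set.

    Precision is the fraction of returned publications whose MeSH terms
    intersect ``term_set``; recall is the fraction of gold PMIDs returned.
    """
    if not returned:
        precision = None
        recall = None if not gold else 0.0
        return PrecisionRecall(precision, recall)
    hits = sum(1 for pub in returned if pub.mesh_terms & term_set)
    precision = hits / len(returned)
    if not gold:
        return PrecisionRecall(precision, None)
    returned_pmids = {pub.pmid for pub in returned}
    return PrecisionRecall(precision, len(returned_pmids & gold) / len(gold))
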