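"""Semantic annotation: prediction tables and evidence records to RDF.

The pipeline mirrors how heterogeneous miRNA-target sources are brought into
one schema:

1. read the per-source "miRNA data" file (miRNA name -> IRI) into a
   dictionary;
2. convert every line of the "gene data" file (miRNA name, gene id, gene
   symbol, score) into exactly four triples — a freshly minted record
   instance typed by the source's record class, linked to the miRNA, linked
   to the target-gene entity, and carrying the score as a typed literal;
3. declare each distinct target gene as a subclass of *miRNA_target_gene*
   with its symbol as label and its numeric id as identifier;
4. annotate publication and GO-annotation evidence the same way;
5. serialize everything to Turtle (see :mod:`mirkg.triples`).

Rows whose miRNA name is absent from the dictionary, or whose score does not
parse, are skipped and counted in the report rather than aborting the run:
prediction dumps and name dictionaries drift, and silent loss is worse than
loud loss.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from decimal import Decimal
from typing import Optional, Sequence

from . import vocab
from .ontology import curie_to_iri
from .triples import InstanceMinter, Literal, Triple, parse_score


class AnnotationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# source configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SourceConfig:
    """Per-database vocabulary bindings for the annotation step."""

    name: str
    record_class: str       # CURIE of the record class
    score_predicate: str    # CURIE of the score datum predicate
    participant_predicate: str = vocab.HAS_PARTICIPANT
    integer_scores: bool = False  # serialize integral scores as xsd:integer


MIRDB = SourceConfig(
    "miRDB", vocab.PREDICTION_FROM_MIRDB, vocab.TARGET_SCORE_IN_MIRDB,
    integer_scores=True,
)
TARGETSCAN = SourceConfig(
    "TargetScan", vocab.PREDICTION_FROM_TARGETSCAN,
    vocab.GENE_CONTEXT_SCORE_IN_TARGETSCAN,
)
MIRANDA = SourceConfig(
    "miRanda", vocab.PREDICTION_FROM_MIRANDA, vocab.MIRSVR_SCORE_IN_MIRANDA,
)

SOURCE_CONFIGS = {cfg.name: cfg for cfg in (MIRDB, TARGETSCAN, MIRANDA)}


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneDataRow:
    """One line of a prediction-table dump."""

    mirna_name: str
    gene_id: str
    gene_symbol: str
    score: str  # raw field; parsed during annotation


@dataclass(frozen=True)
class Publication:
    pmid: int
    mesh_terms: frozenset[str] = frozenset()
    gene_ids: frozenset[str] = frozenset()
    mirna_ids: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.pmid <= 0:
            raise AnnotationError(f"PMID must be positive, got {self.pmid}")


_GO_REF_RE = re.compile(r"^GO_REF:\d{7}$")


@dataclass(frozen=True)
class GoAnnotation:
    gene_id: str
    go_term: str
    go_ref: str

    def __post_init__(self):
        if not _GO_REF_RE.match(self.go_ref):
            raise AnnotationError(f"malformed GO_REF code: {self.go_ref!r}")


class MirnaDictionary(dict):
    """miRNA name -> IRI mapping built from a 2-column "miRNA data" file."""

    blank_lines_skipped: int = 0


class GeneRegistry:
    """Stable gene-entity CURIEs keyed by gene id.

    Symbols are display labels, not identifiers, so identity is the numeric
    gene id; CURIEs are minted first-seen-first in a block separate from the
    record-instance range.
    """

    def __init__(self, prefix: str = "OMIT", start: int = 10000):
        self._minter = InstanceMinter(prefix=prefix, start=start)
        self._by_id: dict[str, str] = {}
        self._symbols: dict[str, str] = {}

    def get_or_create(self, gene_id: str, symbol: Optional[str] = None) -> str:
        curie = self._by_id.get(gene_id)
        if curie is None:
            curie = self._minter.mint()
            self._by_id[gene_id] = curie
        if symbol and gene_id not in self._symbols:
            self._symbols[gene_id] = symbol
        return curie

    def symbol(self, gene_id: str) -> Optional[str]:
        return self._symbols.get(gene_id)

    def items(self):
        return self._by_id.items()


@dataclass
class AnnotationReport:
    rows: int = 0
    accepted: int = 0
    skipped_unknown_mirna: int = 0
    skipped_bad_score: int = 0
    skipped_publications: int = 0

    @property
    def skipped(self) -> int:
        return (
            self.skipped_unknown_mirna
            + self.skipped_bad_score
            + self.skipped_publications
        )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_mirna_dictionary(path, header: bool = True) -> MirnaDictionary:
    """Read the 2-column "miRNA data" file into a name -> IRI dictionary.

    Blank lines are skipped and counted; a name mapped to two different IRIs
    is a hard error.
    """
    out = MirnaDictionary()
    blanks = 0
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle, delimiter="\t")
        for i, row in enumerate(reader):
            if header and i == 0:
                continue
            if not row or not any(cell.strip() for cell in row):
                blanks += 1
                continue
            if len(row) < 2:
                raise AnnotationError(f"{path}: line {i + 1} has fewer than 2 columns")
            name, iri = row[0].strip(), row[1].strip()
            if name in out and out[name] != iri:
                raise AnnotationError(
                    f"miRNA {name!r} mapped to conflicting IRIs: {out[name]} vs {iri}"
                )
            out[name] = iri
    out.blank_lines_skipped = blanks
    return out


def read_gene_data(path, header: bool = True) -> list[GeneDataRow]:
    """Read the 4-column "gene data" file (name, gene id, symbol, score)."""
    rows = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle, delimiter="\t")
        for i, row in enumerate(reader):
            if header and i == 0:
                continue
            if not row or not any(cell.strip() for cell in row):
                continue
            if len(row) < 4:
                raise AnnotationError(f"{path}: line {i + 1} has fewer than 4 columns")
            rows.append(GeneDataRow(*(cell.strip() for cell in row[:4])))
    return rows


def read_publications(path, header: bool = True) -> list[Publication]:
    """Read a publications TSV: pmid, mesh CURIEs, gene ids, miRNA CURIEs
    (multi-valued cells pipe-separated)."""
    def split(cell: str) -> frozenset[str]:
        return frozenset(x.strip() for x in cell.split("|") if x.strip())

    pubs = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle, delimiter="\t")
        for i, row in enumerate(reader):
            if header and i == 0:
                continue
            if not row or not any(cell.strip() for cell in row):
                continue
            pubs.append(
                Publication(
                    pmid=int(row[0]),
                    mesh_terms=split(row[1] if len(row) > 1 else ""),
                    gene_ids=split(row[2] if len(row) > 2 else ""),
                    mirna_ids=split(row[3] if len(row) > 3 else ""),
                )
            )
    return pubs


def read_go_annotations(path, header: bool = True) -> list[GoAnnotation]:
    gos = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle, delimiter="\t")
        for i, row in enumerate(reader):
            if header and i == 0:
                continue
            if not row or not any(cell.strip() for cell in row):
                continue
            gos.append(GoAnnotation(row[0].strip(), row[1].strip(), row[2].strip()))
    return gos


# ---------------------------------------------------------------------------
# annotation proper
# ---------------------------------------------------------------------------

def _score_literal(score: Decimal, cfg: SourceConfig) -> Literal:
    if cfg.integer_scores and score == score.to_integral_value():
        return Literal.integer(int(score))
    return Literal.decimal(score)


def annotate_prediction_rows(
    rows: Sequence[GeneDataRow],
    dictionary: MirnaDictionary,
    minter: InstanceMinter,
    cfg: SourceConfig,
    genes: GeneRegistry,
) -> tuple[list[Triple], AnnotationReport]:
    """Convert prediction-table rows into four triples per accepted row."""
    report = AnnotationReport()
    triples: list[Triple] = []
    record_class_iri = curie_to_iri(cfg.record_class)
    participant = curie_to_iri(cfg.participant_predicate)
    score_pred = curie_to_iri(cfg.score_predicate)
    for row in rows:
        report.rows += 1
        mirna_iri = dictionary.get(row.mirna_name)
        if mirna_iri is None:
            report.skipped_unknown_mirna += 1
            continue
        try:
            score = parse_score(row.score)
        except ValueError:
            report.skipped_bad_score += 1
            continue
        gene_iri = curie_to_iri(genes.get_or_create(row.gene_id, row.gene_symbol))
        inst = curie_to_iri(minter.mint())
        triples.extend(
            [
                Triple(inst, vocab.RDF_TYPE, record_class_iri),
                Triple(inst, participant, mirna_iri),
                Triple(inst, participant, gene_iri),
                Triple(inst, score_pred, _score_literal(score, cfg)),
            ]
        )
        report.accepted += 1
    return triples, report


def declare_gene_class(
    gene_id: str, gene_symbol: str, genes: GeneRegistry
) -> list[Triple]:
    """Declare one target-gene entity.

    Emits the subclass-of-*miRNA_target_gene* triple, the symbol as label,
    and the numeric gene id as identifier so the graph stays self-contained.
    Output is deterministic per gene, so repeated calls add nothing new to a
    deduplicating store.
    """
    if not gene_symbol:
        raise AnnotationError(f"gene {gene_id!r} has an empty symbol")
    gene_iri = curie_to_iri(genes.get_or_create(gene_id, gene_symbol))
    return [
        Triple(gene_iri, vocab.RDFS_SUBCLASSOF, curie_to_iri(vocab.MIRNA_TARGET_GENE)),
        Triple(gene_iri, vocab.RDFS_LABEL, Literal.string(gene_symbol)),
        Triple(gene_iri, vocab.DCTERMS_IDENTIFIER, Literal.string(gene_id)),
    ]


def annotate_evidence(
    pubs: Sequence[Publication],
    gos: Sequence[GoAnnotation],
    minter: InstanceMinter,
    genes: GeneRegistry,
) -> tuple[list[Triple], AnnotationReport]:
    """Annotate publication and GO-annotation evidence records.

    Each publication becomes a typed instance linked to its PMID (integer
    literal), each MeSH term, each gene entity and each miRNA; publications
    linked to neither a gene nor a miRNA are skipped and counted.  Each GO
    record becomes a typed instance linked to its gene, GO term and GO_REF
    code.
    """
    report = AnnotationReport()
    triples: list[Triple] = []
    participant = curie_to_iri(vocab.HAS_PARTICIPANT)
    for pub in pubs:
        report.rows += 1
        if not pub.gene_ids and not pub.mirna_ids:
            report.skipped_publications += 1
            continue
        inst = curie_to_iri(minter.mint())
        triples.append(
            Triple(inst, vocab.RDF_TYPE, curie_to_iri(vocab.INFORMATION_FROM_PUBMED))
        )
        triples.append(
            Triple(inst, curie_to_iri(vocab.HAS_PMID), Literal.integer(pub.pmid))
        )
        for mesh in sorted(pub.mesh_terms):
            triples.append(
                Triple(inst, curie_to_iri(vocab.HAS_MESH_TERM), curie_to_iri(mesh))
            )
        for gene_id in sorted(pub.gene_ids):
            gene_iri = curie_to_iri(genes.get_or_create(gene_id))
            triples.append(Triple(inst, participant, gene_iri))
        for mirna in sorted(pub.mirna_ids):
            triples.append(Triple(inst, participant, curie_to_iri(mirna)))
        report.accepted += 1
    for go in gos:
        report.rows += 1
        inst = curie_to_iri(minter.mint())
        gene_iri = curie_to_iri(genes.get_or_create(go.gene_id))
        triples.extend(
            [
                Triple(inst, vocab.RDF_TYPE, curie_to_iri(vocab.GO_ANNOTATION_RECORD)),
                Triple(inst, participant, gene_iri),
                Triple(inst, curie_to_iri(vocab.HAS_GO_TERM), curie_to_iri(go.go_term)),
                Triple(inst, curie_to_iri(vocab.HAS_GO_REF), Literal.string(go.go_ref)),
            ]
        )
        report.accepted += 1
    return triples, report


def annotate_source(
    mirna_file,
    gene_file,
    cfg: SourceConfig,
    minter: InstanceMinter,
    genes: GeneRegistry,
) -> tuple[list[Triple], AnnotationReport]:
    """File-level wrapper: dictionary + rows + gene-class declarations."""
    dictionary = read_mirna_dictionary(mirna_file)
    rows = read_gene_data(gene_file)
    triples, report = annotate_prediction_rows(rows, dictionary, minter, cfg, genes)
    seen: set[str] = set()
    for row in rows:
        if row.gene_id in seen or row.mirna_name not in dictionary:
            continue
        seen.add(row.gene_id)
        triples.extend(declare_gene_class(row.gene_id, row.gene_symbol, genes))
    return triples, report
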