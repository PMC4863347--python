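"""Seeded synthetic fixtures emulating the pipeline's input universe.

Real inputs to this kind of system are bulk dumps of miRNA-target prediction
databases, a MeSH-style term hierarchy, and publication/GO-annotation
evidence.  None of those can (or should) be downloaded to test the
pipeline, so this module generates structurally faithful stand-ins:

* per-source prediction tables ("miRNA data" + "gene data" files) with
  **exact** requested cardinalities and pairwise target overlaps for a focal
  miRNA — construction is partition-then-assign, not i.i.d. sampling, so
  printed-count reproductions are deterministic and seed-independent while
  scores remain seeded pseudo-random draws from per-source ranges;
* a rooted MeSH-like is_a tree of configurable depth and branching;
* per-gene publication records in which an exactly controlled fraction
  carries the focal MeSH term, plus GO-annotation records.

Everything is deterministic per seed (one root seed fanned out per
generator; no global random state), and two runs with the same spec write
byte-identical files.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import yaml

from . import vocab
from .annotate import GeneDataRow, GoAnnotation, Publication
from .ontology import RelationDef, Term, save_ontology_tables

DEFAULT_SOURCES = ("miRDB", "TargetScan", "miRanda")

#: per-source score ranges: miRDB integer target scores (published range is
#: 50-100), TargetScan context scores and miRanda mirSVR scores (negative
#: decimals).
DEFAULT_SCORE_RANGES = {
    "miRDB": (50, 100),
    "TargetScan": (Decimal("-1.200"), Decimal("-0.010")),
    "miRanda": (Decimal("-3.0000"), Decimal("-0.1000")),
}

GO_TERM_POOL = ("GO_0008150", "GO_0003674", "GO_0005575", "GO_0005634")
GO_REF_POOL = ("GO_REF:0000038", "GO_REF:0000033", "GO_REF:0000041")


class FixtureError(ValueError):
    pass


@dataclass
class FixtureSpec:
    """Cardinalities, overlaps and noise knobs for one synthetic workspace."""

    n_per_source: dict[str, int] = field(
        default_factory=lambda: {"miRDB": 40, "TargetScan": 60, "miRanda": 20}
    )
    overlap: dict[tuple[str, str], int] = field(
        default_factory=lambda: {("miRDB", "TargetScan"): 15}
    )
    mirnas: list[str] = field(default_factory=lambda: ["hsa-miR-125b-5p"])
    score_ranges: dict[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_SCORE_RANGES)
    )
    mesh_depth: int = 2
    mesh_branching: int = 3
    pubs_per_gene: int = 2
    mesh_hit_fraction: float = 0.5
    go_per_gene: int = 2
    extra_targets_per_mirna: int = 3
    seed: int = 0

    def validate(self) -> None:
        for source, n in self.n_per_source.items():
            if n < 0:
                raise FixtureError(f"negative cardinality for {source}")
        for pair, ov in self.overlap.items():
            a, b = pair
            for s in pair:
                if s not in self.n_per_source:
                    raise FixtureError(f"overlap names unknown source {s!r}")
            if ov < 0 or ov > min(self.n_per_source[a], self.n_per_source[b]):
                raise FixtureError(f"infeasible overlap {ov} for pair {pair}")
        # pairwise-disjoint shared regions must fit inside each source
        for s, n in self.n_per_source.items():
            shared = sum(ov for pair, ov in self.overlap.items() if s in pair)
            if shared > n:
                raise FixtureError(
                    f"source {s}: pairwise overlaps sum to {shared} > size {n}"
                )
        if not self.mirnas:
            raise FixtureError("at least one miRNA name is required")
        if not 0.0 <= self.mesh_hit_fraction <= 1.0:
            raise FixtureError("mesh_hit_fraction must be in [0, 1]")
        if self.mesh_depth < 1 or self.mesh_branching < 1:
            raise FixtureError("mesh_depth and mesh_branching must be >= 1")

    @property
    def focal_mirna(self) -> str:
        return self.mirnas[0]


# ---------------------------------------------------------------------------
# prediction databases
# ---------------------------------------------------------------------------

@dataclass
class PredictionFixture:
    mirna_iris: dict[str, str]                 # name -> IRI
    rows: dict[str, list[GeneDataRow]]         # source -> gene-data rows
    focal_targets: dict[str, set[str]]         # source -> gene ids (focal miRNA)
    gene_symbols: dict[str, str]               # gene id -> symbol


def _rng(spec_seed: int, *scope: str) -> random.Random:
    return random.Random(":".join((str(spec_seed),) + scope))


def _draw_score(rng: random.Random, source: str, ranges) -> str:
    lo, hi = ranges.get(source, DEFAULT_SCORE_RANGES.get(source, (0, 100)))
    if isinstance(lo, int) and isinstance(hi, int):
        return str(rng.randint(lo, hi))
    lo_d, hi_d = Decimal(str(lo)), Decimal(str(hi))
    places = max(-lo_d.as_tuple().exponent, -hi_d.as_tuple().exponent, 1)
    value = lo_d + (hi_d - lo_d) * Decimal(str(rng.random()))
    return str(value.quantize(Decimal(1).scaleb(-places)))


def gen_prediction_records(spec: FixtureSpec) -> PredictionFixture:
    """Build the per-source prediction tables in memory.

    The focal (first) miRNA receives exactly the requested per-source target
    counts and pairwise overlaps (three-way intersections empty); any
    further miRNAs receive ``extra_targets_per_mirna`` targets per source.
    """
    spec.validate()
    sources = sorted(spec.n_per_source)
    # disjoint shared regions per sorted pair, then unique remainders
    regions: list[tuple[frozenset[str], int]] = []
    for pair in sorted(spec.overlap):
        regions.append((frozenset(pair), spec.overlap[pair]))
    for s in sources:
        shared = sum(ov for members, ov in regions if s in members)
        regions.append((frozenset([s]), spec.n_per_source[s] - shared))

    gene_symbols: dict[str, str] = {}
    focal_targets: dict[str, set[str]] = {s: set() for s in sources}
    counter = 0
    for members, size in regions:
        for _ in range(size):
            gene_id = str(100001 + counter)
            gene_symbols[gene_id] = f"GENE{counter:05d}"
            counter += 1
            for s in members:
                focal_targets[s].add(gene_id)

    mirna_iris = {
        name: vocab.OBO_BASE + f"NCRO_{100001 + i:07d}"
        for i, name in enumerate(spec.mirnas)
    }

    rows: dict[str, list[GeneDataRow]] = {}
    for s in sources:
        rng = _rng(spec.seed, "scores", s)
        source_rows = [
            GeneDataRow(
                spec.focal_mirna,
                gid,
                gene_symbols[gid],
                _draw_score(rng, s, spec.score_ranges),
            )
            for gid in sorted(focal_targets[s])
        ]
        pool = sorted(focal_targets[s])
        for name in spec.mirnas[1:]:
            for gid in pool[: spec.extra_targets_per_mirna]:
                source_rows.append(
                    GeneDataRow(
                        name, gid, gene_symbols[gid],
                        _draw_score(rng, s, spec.score_ranges),
                    )
                )
        rows[s] = source_rows
    return PredictionFixture(mirna_iris, rows, focal_targets, gene_symbols)


def gen_prediction_dbs(spec: FixtureSpec, out_dir) -> dict[str, tuple[Path, Path]]:
    """Write per-source ("miRNA data", "gene data") TSV file pairs."""
    fixture = gen_prediction_records(spec)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, tuple[Path, Path]] = {}
    for source, source_rows in sorted(fixture.rows.items()):
        mirna_path = out_dir / f"{source}_mirna_data.tsv"
        gene_path = out_dir / f"{source}_gene_data.tsv"
        lines = ["mirna_name\tiri"]
        lines += [f"{name}\t{iri}" for name, iri in fixture.mirna_iris.items()]
        mirna_path.write_text("".join(l + "\n" for l in lines), encoding="utf-8")
        lines = ["mirna_name\tgene_id\tgene_symbol\tscore"]
        lines += [
            f"{r.mirna_name}\t{r.gene_id}\t{r.gene_symbol}\t{r.score}"
            for r in source_rows
        ]
        gene_path.write_text("".join(l + "\n" for l in lines), encoding="utf-8")
        paths[source] = (mirna_path, gene_path)
    return paths


# ---------------------------------------------------------------------------
# MeSH hierarchy
# ---------------------------------------------------------------------------

def gen_mesh_hierarchy(
    depth: int, branching: int, seed: int = 0
) -> tuple[list[Term], str]:
    """A rooted MeSH-like tree: ``depth`` levels below the root, each node
    with ``branching`` children; returns (terms, root id).

    Node count is the geometric sum over levels; every non-root node has
    exactly one parent.  The seed only permutes which numeric ids land on
    which tree position.
    """
    if depth < 1 or branching < 1:
        raise FixtureError("depth and branching must be >= 1")
    total = sum(branching ** level for level in range(depth + 1))
    numbers = list(range(1, total + 1))
    tail = numbers[1:]
    _rng(seed, "mesh-ids").shuffle(tail)  # root keeps the first id
    numbers[1:] = tail
    curies = [f"MESH_{n:07d}" for n in numbers]

    terms: list[Term] = []
    terms.append(Term(curies[0], "mesh_root", frozenset(), "MeSH"))
    # breadth-first: node k (zero-based) at level l has parent (k-1)//branching
    for k in range(1, total):
        parent = curies[(k - 1) // branching]
        terms.append(
            Term(curies[k], f"mesh_term_{k:04d}", frozenset([parent]), "MeSH")
        )
    return terms, curies[0]


# ---------------------------------------------------------------------------
# publications and GO annotations
# ---------------------------------------------------------------------------

def _round_half_up(value: Decimal) -> int:
    return int(value.quantize(Decimal(1), rounding=ROUND_HALF_UP))


def gen_publications(
    genes: Sequence[str],
    mirna: str,
    spec: FixtureSpec,
    focal_term: str,
    decoy_terms: Sequence[str],
    start_pmid: int = 10_000_001,
) -> tuple[list[Publication], list[GoAnnotation]]:
    """Publication and GO-annotation records for a gene list.

    Every publication links its gene and the miRNA (given as a CURIE).  Per
    gene, exactly ``round(mesh_hit_fraction * pubs_per_gene)`` publications
    carry the focal MeSH term; the rest carry decoy terms only.  Decoy terms
    should be hierarchy-unrelated to the focal term when expansion modes are
    under test.
    """
    if not genes:
        raise FixtureError("genes must be non-empty")
    if not decoy_terms:
        raise FixtureError("at least one decoy MeSH term is required")
    rng = _rng(spec.seed, "pubs")
    pubs: list[Publication] = []
    gos: list[GoAnnotation] = []
    pmid = start_pmid
    fraction = Decimal(str(spec.mesh_hit_fraction))
    for gene in genes:
        n = spec.pubs_per_gene
        hits = _round_half_up(fraction * n)
        for j in range(n):
            if j < hits:
                mesh = frozenset([focal_term, rng.choice(decoy_terms)])
            else:
                mesh = frozenset([rng.choice(decoy_terms)])
            pubs.append(
                Publication(
                    pmid=pmid,
                    mesh_terms=mesh,
                    gene_ids=frozenset([gene]),
                    mirna_ids=frozenset([mirna]),
                )
            )
            pmid += 1
        for j in range(spec.go_per_gene):
            gos.append(
                GoAnnotation(
                    gene_id=gene,
                    go_term=GO_TERM_POOL[j % len(GO_TERM_POOL)],
                    go_ref=GO_REF_POOL[j % len(GO_REF_POOL)],
                )
            )
    return pubs, gos


def write_publications_tsv(pubs: Sequence[Publication], path) -> Path:
    path = Path(path)
    lines = ["pmid\tmesh_terms\tgene_ids\tmirna_ids"]
    for pub in pubs:
        lines.append(
            "\t".join(
                [
                    str(pub.pmid),
                    "|".join(sorted(pub.mesh_terms)),
                    "|".join(sorted(pub.gene_ids)),
                    "|".join(sorted(pub.mirna_ids)),
                ]
            )
        )
    path.write_text("".join(l + "\n" for l in lines), encoding="utf-8")
    return path


def write_go_tsv(gos: Sequence[GoAnnotation], path) -> Path:
    path = Path(path)
    lines = ["gene_id\tgo_term\tgo_ref"]
    lines += [f"{g.gene_id}\t{g.go_term}\t{g.go_ref}" for g in gos]
    path.write_text("".join(l + "\n" for l in lines), encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# vocabulary terms + full workspace
# ---------------------------------------------------------------------------

def vocabulary_terms() -> list[Term]:
    """Class terms for the annotation vocabulary, with a shallow hierarchy."""
    ice = vocab.INFORMATION_CONTENT_ENTITY
    md = vocab.MEASUREMENT_DATUM
    pred_db = "OMIT_0000019"  # information_from_miRNA_target_prediction_database
    terms = [
        Term(ice, "information content entity", frozenset(), "class"),
        Term(md, "measurement datum", frozenset([ice]), "class"),
        Term(pred_db, "information_from_miRNA_target_prediction_database",
             frozenset([ice]), "class"),
        Term(vocab.PREDICTION_FROM_MIRDB, "prediction_from_miRDB",
             frozenset([pred_db]), "class"),
        Term(vocab.PREDICTION_FROM_TARGETSCAN, "prediction_from_TargetScan",
             frozenset([pred_db]), "class"),
        Term(vocab.PREDICTION_FROM_MIRANDA, "prediction_from_miRanda",
             frozenset([pred_db]), "class"),
        Term(vocab.TARGET_SCORE_IN_MIRDB, "target_score_in_miRDB",
             frozenset([md]), "class"),
        Term(vocab.GENE_CONTEXT_SCORE_IN_TARGETSCAN,
             "gene_context_score_in_TargetScan", frozenset([md]), "class"),
        Term(vocab.MIRSVR_SCORE_IN_MIRANDA, "mirSVR_score_in_miRanda",
             frozenset([md]), "class"),
        Term(vocab.INFORMATION_FROM_PUBMED, "information_from_PubMed",
             frozenset([ice]), "class"),
        Term(vocab.GO_ANNOTATION_RECORD, "GO_annotation_record",
             frozenset([ice]), "class"),
        Term(vocab.MIRNA_TARGET_GENE, "miRNA_target_gene", frozenset(), "class"),
        Term(vocab.HUMAN_MIRNA, "human_miRNA", frozenset(), "class"),
    ]
    return terms


@dataclass
class Workspace:
    """Paths and key identifiers of a generated fixture workspace."""

    root: Path
    term_table: Path
    relation_table: Path
    source_files: dict[str, tuple[Path, Path]]
    publications: Path
    go_annotations: Path
    config: Path
    focal_mirna: str
    focal_mesh_term: str
    mesh_root: str
    fixture: PredictionFixture


def build_workspace(spec: FixtureSpec, out_dir) -> Workspace:
    """Write a complete, self-consistent workspace: ontology tables,
    per-source prediction dumps, evidence tables and a CLI config file."""
    spec.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    fixture = gen_prediction_records(spec)
    source_files = gen_prediction_dbs(spec, out_dir)

    mesh_terms, mesh_root = gen_mesh_hierarchy(
        spec.mesh_depth, spec.mesh_branching, spec.seed
    )
    # focal term: first child of the root (has both ancestors and, for
    # depth >= 2, descendants); decoys: the root's other children subtrees
    children = [t for t in mesh_terms if mesh_root in t.parents]
    focal = children[0].id if children else mesh_root

    terms = vocabulary_terms()
    terms += [
        Term(
            iri.removeprefix(vocab.OBO_BASE), name,
            frozenset([vocab.HUMAN_MIRNA]), "miRNA",
        )
        for name, iri in fixture.mirna_iris.items()
    ]
    terms += mesh_terms
    relations = [
        RelationDef(vocab.HAS_PARTICIPANT, "has participant",
                    vocab.INFORMATION_CONTENT_ENTITY, vocab.MIRNA_TARGET_GENE),
        RelationDef(vocab.PART_OF, "part of",
                    vocab.MEASUREMENT_DATUM, vocab.PREDICTION_FROM_MIRDB),
        RelationDef(vocab.HAS_MESH_TERM, "has_MeSH_term",
                    vocab.INFORMATION_FROM_PUBMED, mesh_root),
    ]
    term_table = out_dir / "ontology_terms.tsv"
    relation_table = out_dir / "ontology_relations.tsv"
    save_ontology_tables(terms, relations, term_table, relation_table)

    focal_mirna_curie = fixture.mirna_iris[spec.focal_mirna].removeprefix(
        vocab.OBO_BASE
    )
    all_genes = sorted(
        set().union(*fixture.focal_targets.values())
        if fixture.focal_targets
        else set()
    )
    subtree = {focal}
    frontier = [focal]
    by_parent: dict[str, list[str]] = {}
    for t in mesh_terms:
        for p in t.parents:
            by_parent.setdefault(p, []).append(t.id)
    while frontier:
        node = frontier.pop()
        for child in by_parent.get(node, []):
            if child not in subtree:
                subtree.add(child)
                frontier.append(child)
    decoys = [t.id for t in mesh_terms if t.id not in subtree and t.id != mesh_root]
    if not decoys:
        decoys = [mesh_root]

    if all_genes:
        pubs, gos = gen_publications(
            all_genes, focal_mirna_curie, spec, focal, decoys
        )
    else:
        pubs, gos = [], []
    publications = write_publications_tsv(pubs, out_dir / "publications.tsv")
    go_annotations = write_go_tsv(gos, out_dir / "go_annotations.tsv")

    config = out_dir / "config.yaml"
    config.write_text(
        yaml.safe_dump(
            {
                "seed": spec.seed,
                "minter_start": 900000,
                "ontology": {
                    "terms": term_table.name,
                    "relations": relation_table.name,
                },
                "sources": [
                    {
                        "name": source,
                        "mirna_data": paths[0].name,
                        "gene_data": paths[1].name,
                    }
                    for source, paths in sorted(source_files.items())
                ],
                "evidence": {
                    "publications": publications.name,
                    "go_annotations": go_annotations.name,
                },
                "focal_mirna": spec.focal_mirna,
                "focal_mesh_term": focal,
            },
            sort_keys=True,
        ),
        encoding="utf-8",
    )
    return Workspace(
        root=out_dir,
        term_table=term_table,
        relation_table=relation_table,
        source_files=source_files,
        publications=publications,
        go_annotations=go_annotations,
        config=config,
        focal_mirna=spec.focal_mirna,
        focal_mesh_term=focal,
        mesh_root=mesh_root,
        fixture=fixture,
    )
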