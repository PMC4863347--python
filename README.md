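# mirkg

Ontology-driven integration and semantic search of miRNA–target
interaction data.

## The problem

microRNAs (miRNAs) regulate gene expression by binding target mRNAs, and
working out what a miRNA does in practice means cross-referencing several
mutually inconsistent resources: target-prediction databases (miRDB with
integer target scores, TargetScan with context scores, miRanda with mirSVR
scores), the literature (PubMed records annotated with MeSH terms), and GO
annotations. The sources are heterogeneous in both syntax and meaning, so
answering a question like *"what is the role of hsa-miR-125b-5p in cancer
drug resistance?"* by hand means many separate queries and a lot of manual
set intersection.

`mirkg` addresses this by **semantic annotation**: every source record is
converted into RDF triples whose classes and predicates come from a shared
OBO-style ontology vocabulary (terms such as `NCRO_0000025`
*miRNA_target_gene*, `OMIT_0000020` *prediction_from_miRDB*, `RO_0000057`
*has participant*), accumulated into one triple store, and queried
uniformly. For each line of a prediction dump
(miRNA name, gene id, gene symbol, score) the annotator emits exactly four
triples:

```
inst_i  rdf:type          prediction_from_<db>
inst_i  has_participant   <miRNA IRI>
inst_i  has_participant   <gene IRI>
inst_i  <db score datum>  "score"^^xsd:integer|decimal
```

where `inst_i` is a freshly minted instance IRI from a reserved 7-digit
block. Distinct target genes are declared as subclasses of
*miRNA_target_gene* with their symbol as label. The search engine then
answers integrated queries over the store:

* **any / all / specific database** — union, intersection, or a single
  source's predicted-target set for a miRNA (a configured source with no
  predictions for that miRNA makes the intersection empty);
* **MeSH-filtered literature** — a publication attaches to a result row only
  if it links both the gene and the miRNA and, when a MeSH filter is set,
  carries a term from the filter's expansion: the exact term, its broader
  (ancestor) terms under transitive `is_a` closure, its narrower
  (descendant) terms, or all of these;
* score-sorted, paginated result tables with per-row GO annotations, and
  CSV/TSV/gene-list downloads with reproducible
  `Query_Results_for_<mirna>-<date>` filenames.

Evaluation helpers compute the MeSH filter's publication-reduction
percentage, `round(100·(before−after)/before)`, and precision/recall of a
returned publication set against a supplied gold standard.

Because real miRDB/TargetScan/miRanda dumps and PubMed records cannot be
bundled, the `fixtures` module generates structurally faithful synthetic
inputs with **exact** requested cardinalities and overlaps (see
`docs/methods.md`), so the whole pipeline is testable offline.

Intended users: bioinformaticians studying miRNA regulation who want a
scriptable, reproducible version of this integration workflow, and
developers of semantic-search tooling who need a compact, fully tested
reference pipeline.

## Worked example

Generate a small workspace (6 miRDB targets, 9 TargetScan targets, 4
shared, empty miRanda; 4 publications per gene, half carrying the focal
MeSH term), annotate it, and search:

```bash
cat > spec.yaml <<'EOF'
n_per_source: {miRDB: 6, TargetScan: 9, miRanda: 0}
overlap: {miRDB/TargetScan: 4}
mirnas: [hsa-miR-125b-5p]
pubs_per_gene: 4
mesh_hit_fraction: 0.5
seed: 42
EOF
mirkg fixtures --spec spec.yaml ws
mirkg annotate --config ws/config.yaml --out graph.ttl
# -> 423 distinct triples -> graph.ttl
mirkg search --config ws/config.yaml --store graph.ttl \
      --mirna hsa-miR-125b-5p --mesh-term MESH_0000002 --out results.json
mirkg export --results results.json --mirna-label hsa-miR-125b-5p \
      --date 2015-12-05 --gene-list --out-dir exports
```

The search reports `"total_distinct_targets": 11` — the union 6 + 9 − 4 of
the two covering sources — and each row keeps only the 2 of its 4
publications that carry the focal MeSH term (`mesh_hit_fraction: 0.5`).
The export writes `Query_Results_for_hsa-miR-125b-5p-2015-12-05.csv`,
whose first data line reads

```
GENE00000,100001,TargetScan|miRDB,79,-1.11,,10000001|10000002,GO_0003674(GO_REF:0000033)|GO_0008150(GO_REF:0000038)
```

i.e. target symbol, gene id, predicting databases, per-database scores
(miRDB target score 79, TargetScan context score −1.11, no miRanda
prediction), the MeSH-filtered PMIDs, and GO annotations with their GO_REF
evidence codes. Re-running with `--db-filter all` returns an empty table:
miRanda has no predictions for this miRNA, so the all-databases
intersection is empty. The same calls are available as library functions
(`mirkg.search.search`, `mirkg.annotate.annotate_prediction_rows`, ...).

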