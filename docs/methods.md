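# Methods

This note documents the model behind `mirkg`, the choices made where the
design was genuinely open, and what the synthetic fixtures do and do not
show about real data.

## The annotation model

Each heterogeneous source is mapped onto one RDF schema drawn from an
OBO-style vocabulary (`mirkg.vocab`). A prediction-table line becomes a
*record instance*: a minted individual typed by the source's record class
(`prediction_from_miRDB` / `_TargetScan` / `_miRanda`), linked by
*has participant* (`RO_0000057`) to the miRNA (IRI resolved through the
source's miRNA-name dictionary) and to the target-gene entity, and carrying
the prediction score through the source's score-datum predicate
(`target_score_in_miRDB`, `gene_context_score_in_TargetScan`,
`mirSVR_score_in_miRanda`). This is the canonical "four triples per line"
contract, property-tested as `4 × (rows − skipped)` for arbitrary inputs.

Choices made here:

* **Instance minting.** Sequential, zero-padded 7-digit ids from a reserved
  block (default start 0900000) in a configurable prefix. Determinism in
  input order — not uniqueness alone — is the requirement, because a
  re-annotated workspace must serialize byte-identically.
* **Gene identity.** Gene entities are keyed by numeric gene id; symbols
  are labels. Each distinct gene is declared once: a
  `rdfs:subClassOf miRNA_target_gene` triple, a `rdfs:label` triple with
  the symbol, and a `dcterms:identifier` triple with the gene id. The
  identifier triple makes the Turtle graph self-contained: a store
  reconstructed from the file alone can report gene ids in result tables
  without a sidecar mapping.
* **Score datatypes.** miRDB target scores are integers in their published
  0–100 scale and serialize as `xsd:integer` when integral; TargetScan and
  miRanda scores are negative decimals and serialize as `xsd:decimal`.
* **Unresolvable rows.** A miRNA name missing from the dictionary, or a
  non-numeric score, skips the row and increments a counter in the
  annotation report. Dumps and dictionaries drift; aborting would make the
  pipeline unusable, silent dropping would hide data loss.
* **Score attachment.** The score sits directly on the record instance.
  A fully reified alternative (a measurement-datum individual linked by
  *part of*) is a recognized modelling pattern for the same information but
  would break the four-triple contract, so it was not implemented; mixing
  the two patterns in one store is the worst option and is avoided by
  construction. A one-row worked example therefore yields 7 triples:
  4 record triples + the 3 gene-declaration triples.

Evidence records follow the same scheme: a publication instance
(`information_from_PubMed`) linked to its PMID (integer literal), its MeSH
terms, and the gene and miRNA entities it mentions; a GO-annotation
instance linked to gene, GO term and GO_REF code. Publications with
neither a gene nor a miRNA link cannot contribute to any search result and
are skipped with a report count.

## Turtle I/O

Parsing is delegated to rdflib and accepts general Turtle restricted to
IRI subjects/predicates and integer/decimal/string literals (blank nodes
and other datatypes are rejected loudly). Serialization is a small
deterministic emitter — prefix block, then one line per triple sorted by
subject, predicate, object — because byte-identical re-runs are part of
the pipeline's contract and generic serializers do not promise stable line
order. Tests assert that the emitter's output round-trips through rdflib
and that serialize∘parse / parse∘serialize are identities on this subset.

## Ontology model

The ontology is two flat TSV tables (terms with pipe-separated parents and
a category; relations with domain/range), not OWL: the search engine needs
labels, the `is_a` DAG and relation signatures, and description-logic
semantics would buy nothing here. Load-time validation: duplicate CURIEs
and label collisions within a category are hard errors (label lookup and
autocomplete must be unambiguous); cycles are hard errors naming the cycle;
dangling parents are collected into a report rather than dropped, so
fixture truncation is visible. Broader/narrower term sets are transitive
closures over the DAG (networkx reachability), tested against an
independent path-enumeration oracle. Label matching for autocomplete is
case-folded substring only — no stemming, no fuzzy matching — since
anything cleverer would make "partial or exact" behaviour unpredictable.

## Query evaluation

The triple store is an in-memory set with subject/predicate/object posting
lists. Queries are programmatic lists of triple patterns (constants or
named variables) evaluated conjunctively with set semantics
(duplicate-free solutions, like SPARQL `SELECT DISTINCT`), plus
substring/regex filters on bound variables. Join order is chosen
internally (left-to-right with index-backed candidate lookup) and is
irrelevant to the solution set — property-tested against a brute-force
oracle that enumerates every assignment of store triples to patterns, for
random stores and random 1–3-pattern queries. A SPARQL *text* parser is
deliberately out of scope; the behaviour, not the syntax, is the point,
and an endpoint adapter could be layered on later.

## Search semantics

* Candidate set: union over sources (`any`), intersection over **all
  configured** sources (`all`), or one source (`specific`). Under `all`, a
  configured source with zero predictions for the miRNA forces an empty
  result — absence of coverage is evidence, not noise. (A variant that
  intersects only covering sources can be had by passing just those
  sources' configs to `search`.)
* Publication attachment requires the gene link **and** the miRNA link
  **and** (when filtering) a MeSH term inside the expansion. Default
  expansion mode is `exact`; broader/narrower expansion is a user choice.
* `total_distinct_targets` counts rows after the database and evidence
  filters, before pagination.
* Sorting: descending by the chosen source's score; rows without that
  score trail; ties and trailing rows order by gene symbol — fully
  deterministic.
* `percent_reduction` rounds to the nearest integer percent, halves away
  from zero; this rounding reproduces all published example pairs used in
  the test suite, e.g. (50,16)→68 %, (13,2)→85 %, (31,3)→90 %.
* Recall is a function of a *supplied* gold-standard PMID set only; the
  package takes no position on how such a set is curated.

## Synthetic fixtures

`mirkg.fixtures` emulates the input universe: per-source prediction dumps,
a MeSH-like hierarchy, publications and GO annotations. Design:

* **Exact counts by construction.** The focal miRNA's per-source target
  counts and pairwise overlaps are built by partitioning a gene pool into
  shared and unique regions and assigning ids, not by i.i.d. sampling, so
  requested cardinalities hold exactly, for every seed. Pairwise overlaps
  are taken as disjoint (empty three-way intersection); infeasible
  overlap maps raise.
* **Seeding.** One root seed is fanned out into independent
  `random.Random` streams per generator (scores per source, id shuffling,
  publication terms); there is no global random state, and identical specs
  write byte-identical files.
* **Defaults.** miRDB scores are integers drawn from (50, 100) — the range
  the database actually publishes; TargetScan context scores from
  (−1.2, −0.01) and miRanda mirSVR scores from (−3.0, −0.1), matching the
  sign and order of magnitude of the real scores. The MeSH tree defaults
  to depth 2, branching 3; publications default to 2 per gene with a 0.5
  focal-term hit fraction. `pubs_per_gene` applies uniformly per gene and
  `round(mesh_hit_fraction · pubs_per_gene)` publications per gene carry
  the focal term exactly (half-up rounding).
* **Decoy MeSH terms** for non-hit publications are drawn from outside the
  focal term's subtree, so exact- and narrower-mode filtered counts are
  exactly predictable from the hit fraction.

What the fixtures do **not** emulate: realistic score distributions or
score correlation between databases, real gene identifiers/symbols, real
PMIDs or MeSH content, publications mentioning many genes or many miRNAs,
and annotation noise beyond the skip paths (wrong-but-parseable fields).
Passing tests therefore demonstrate the integration, filtering, counting
and serialization machinery — not robustness to the messiness of real
dumps, which would need source-specific cleaning upstream.

## Problem sizes and verification

The test suite covers every operation with unit tests plus seeded property
tests (hypothesis, derandomized, ≤ 40 examples per property; brute-force
oracles for closure, pattern matching and sorting; 6 random end-to-end
workspace replicates), and an end-to-end acceptance suite at the
demonstration cardinalities (476/924/323 targets, 200-publication
precision fixture). `scripts/acceptance.py` recomputes the headline
numbers from scratch through the full
fixtures → annotate → Turtle → parse → store → search path. The entire
suite runs in a few seconds on one CPU.

## Known limitations

* No OWL import closure or DL reasoning; `is_a` is the only hierarchy
  relation used for expansion.
* The query engine supports conjunctive patterns with filters — no
  OPTIONAL/UNION/aggregation — and the store is purely in-memory.
* One consistent IRI per miRNA is assumed; reconciling multiple historical
  ids for the same miRNA across ontology versions is out of scope.
* `precision_recall` flags, rather than defines, the degenerate cases
  (empty returned set, empty gold set) by returning `None`.
* The CLI mirrors a single-user workflow; there is no HTTP service or
  concurrent store access.
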