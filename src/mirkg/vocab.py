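"""Controlled vocabulary used throughout the knowledge graph.

Identifiers follow the OBO CURIE convention ``PREFIX_NNNNNNN`` and expand
under the OBO PURL base.  The terms fall into three groups:

* terms imported from public ontologies (NCRO, RO, BFO, IAO) whose ids are
  stable and well known, e.g. ``NCRO_0000025`` (*miRNA_target_gene*) and
  ``RO_0000057`` (*has participant*);
* OMIT-style record and score-datum classes for the three prediction
  databases; ``OMIT_0000020`` (*prediction_from_miRDB*) and ``OMIT_0000108``
  (*target_score_in_miRDB*) are the published ids, the remaining four are
  fixture-assigned ids kept in a reserved low block;
* fixture-assigned evidence vocabulary (publication and GO-annotation record
  classes and their data predicates).
"""

OBO_BASE = "http://purl.obolibrary.org/obo/"

RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
RDFS_NS = "http://www.w3.org/2000/01/rdf-schema#"
XSD_NS = "http://www.w3.org/2001/XMLSchema#"
DCTERMS_NS = "http://purl.org/dc/terms/"

RDF_TYPE = RDF_NS + "type"
RDFS_LABEL = RDFS_NS + "label"
RDFS_SUBCLASSOF = RDFS_NS + "subClassOf"
DCTERMS_IDENTIFIER = DCTERMS_NS + "identifier"

XSD_INTEGER = XSD_NS + "integer"
XSD_DECIMAL = XSD_NS + "decimal"
XSD_STRING = XSD_NS + "string"

# -- imported terms and relations (stable public ids) -----------------------
MIRNA_TARGET_GENE = "NCRO_0000025"      # class of predicted target genes
HUMAN_MIRNA = "NCRO_0000810"
HAS_PARTICIPANT = "RO_0000057"
PARTICIPATES_IN = "RO_0000056"
PART_OF = "BFO_0000050"
INFORMATION_CONTENT_ENTITY = "IAO_0000030"
MEASUREMENT_DATUM = "IAO_0000109"

# -- prediction-record classes and score predicates --------------------------
PREDICTION_FROM_MIRDB = "OMIT_0000020"
TARGET_SCORE_IN_MIRDB = "OMIT_0000108"
# fixture-assigned ids (consistent within this package's graphs):
PREDICTION_FROM_TARGETSCAN = "OMIT_0000021"
PREDICTION_FROM_MIRANDA = "OMIT_0000022"
GENE_CONTEXT_SCORE_IN_TARGETSCAN = "OMIT_0000109"
MIRSVR_SCORE_IN_MIRANDA = "OMIT_0000110"

# -- evidence vocabulary (fixture-assigned ids) ------------------------------
INFORMATION_FROM_PUBMED = "OMIT_0000031"
HAS_PMID = "OMIT_0000032"
HAS_MESH_TERM = "OMIT_0000033"
GO_ANNOTATION_RECORD = "OMIT_0000034"
HAS_GO_TERM = "OMIT_0000035"
HAS_GO_REF = "OMIT_0000036"

#: labels for the vocabulary terms above, keyed by CURIE; used by the fixture
#: generator to seed the ontology tables so label lookup works end to end.
VOCAB_LABELS = {
    MIRNA_TARGET_GENE: "miRNA_target_gene",
    HUMAN_MIRNA: "human_miRNA",
    INFORMATION_CONTENT_ENTITY: "information content entity",
    MEASUREMENT_DATUM: "measurement datum",
    PREDICTION_FROM_MIRDB: "prediction_from_miRDB",
    PREDICTION_FROM_TARGETSCAN: "prediction_from_TargetScan",
    PREDICTION_FROM_MIRANDA: "prediction_from_miRanda",
    TARGET_SCORE_IN_MIRDB: "target_score_in_miRDB",
    GENE_CONTEXT_SCORE_IN_TARGETSCAN: "gene_context_score_in_TargetScan",
    MIRSVR_SCORE_IN_MIRANDA: "mirSVR_score_in_miRanda",
    INFORMATION_FROM_PUBMED: "information_from_PubMed",
    HAS_PMID: "has_PMID",
    HAS_MESH_TERM: "has_MeSH_term",
    GO_ANNOTATION_RECORD: "GO_annotation_record",
    HAS_GO_TERM: "has_GO_term",
    HAS_GO_REF: "has_GO_REF",
}

VOCAB_RELATIONS = {
    HAS_PARTICIPANT: "has participant",
    PARTICIPATES_IN: "participates in",
    PART_OF: "part of",
}
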