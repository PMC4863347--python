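"""YAML workspace configuration: source bindings, ontology paths, evidence.

A workspace config names the ontology tables, the per-source ("miRNA data",
"gene data") file pairs, the evidence tables, and the instance-minter start.
Relative paths resolve against the config file's directory, so a generated
fixture workspace is relocatable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

from .annotate import (
    SOURCE_CONFIGS,
    AnnotationReport,
    GeneRegistry,
    SourceConfig,
    annotate_evidence,
    annotate_source,
    read_go_annotations,
    read_publications,
)
from .ontology import OntologyGraph, load_ontology
from .search import EvidenceSet
from .store import TripleStore
from .triples import InstanceMinter, Triple


class ConfigError(ValueError):
    pass


@dataclass
class SourceFiles:
    config: SourceConfig
    mirna_data: Path
    gene_data: Path


@dataclass
class WorkspaceConfig:
    root: Path
    sources: list[SourceFiles]
    term_table: Path
    relation_table: Optional[Path]
    publications: Optional[Path]
    go_annotations: Optional[Path]
    minter_start: int = 900000
    seed: int = 0
    focal_mirna: Optional[str] = None
    focal_mesh_term: Optional[str] = None


def load_config(path) -> WorkspaceConfig:
    path = Path(path)
    root = path.parent
    with open(path, encoding="utf-8") as handle:
        raw = yaml.safe_load(handle) or {}

    def resolve(name: Optional[str]) -> Optional[Path]:
        if not name:
            return None
        p = Path(name)
        return p if p.is_absolute() else root / p

    ontology = raw.get("ontology") or {}
    term_table = resolve(ontology.get("terms"))
    if term_table is None:
        raise ConfigError(f"{path}: ontology.terms is required")
    sources = []
    for entry in raw.get("sources", []):
        name = entry.get("name")
        if name not in SOURCE_CONFIGS:
            raise ConfigError(f"{path}: unknown source {name!r}")
        sources.append(
            SourceFiles(
                config=SOURCE_CONFIGS[name],
                mirna_data=resolve(entry["mirna_data"]),
                gene_data=resolve(entry["gene_data"]),
            )
        )
    evidence = raw.get("evidence") or {}
    return WorkspaceConfig(
        root=root,
        sources=sources,
        term_table=term_table,
        relation_table=resolve(ontology.get("relations")),
        publications=resolve(evidence.get("publications")),
        go_annotations=resolve(evidence.get("go_annotations")),
        minter_start=int(raw.get("minter_start", 900000)),
        seed=int(raw.get("seed", 0)),
        focal_mirna=raw.get("focal_mirna"),
        focal_mesh_term=raw.get("focal_mesh_term"),
    )


def load_ontology_from(cfg: WorkspaceConfig) -> OntologyGraph:
    return load_ontology(cfg.term_table, cfg.relation_table)


def load_evidence(cfg: WorkspaceConfig) -> EvidenceSet:
    pubs = read_publications(cfg.publications) if cfg.publications else []
    gos = read_go_annotations(cfg.go_annotations) if cfg.go_annotations else []
    return EvidenceSet(publications=pubs, go_annotations=gos)


def annotate_workspace(
    cfg: WorkspaceConfig, include_evidence: bool = True
) -> tuple[list[Triple], dict[str, AnnotationReport]]:
    """Annotate every configured source (plus evidence) into one triple list."""
    minter = InstanceMinter(start=cfg.minter_start)
    genes = GeneRegistry()
    triples: list[Triple] = []
    reports: dict[str, AnnotationReport] = {}
    for source in cfg.sources:
        ts, report = annotate_source(
            source.mirna_data, source.gene_data, source.config, minter, genes
        )
        triples.extend(ts)
        reports[source.config.name] = report
    if include_evidence and (cfg.publications or cfg.go_annotations):
        ev = load_evidence(cfg)
        ts, report = annotate_evidence(
            ev.publications, ev.go_annotations, minter, genes
        )
        triples.extend(ts)
        reports["evidence"] = report
    return triples, reports


def build_store(triples) -> TripleStore:
    return TripleStore(triples)
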