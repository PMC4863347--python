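"""Result-table and gene-list export.

Filenames follow the download convention ``Query_Results_for_<mirna>-<date>``
(``.csv`` or ``.txt``) and ``Target_List_for_<mirna>-<date>.txt``.  The date
is injected through :class:`ExportSpec` rather than read from the wall
clock, so exports are reproducible and byte-identical on re-run.  Files are
UTF-8 with LF line endings; multi-valued cells are pipe-joined; CSV quoting
follows RFC 4180.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .search import ResultRow, ResultTable


class ExportError(ValueError):
    pass


DEFAULT_SOURCE_COLUMNS = (
    ("miRDB", "miRDB_target_score"),
    ("TargetScan", "TargetScan_context_score"),
    ("miRanda", "miRanda_mirSVR_score"),
)


@dataclass(frozen=True)
class ExportSpec:
    mirna_label: str
    date: dt.date
    format: str = "csv"          # csv | tsv
    scope: str = "full_table"    # full_table | selected_targets | all_targets

    def __post_init__(self):
        if self.format not in ("csv", "tsv"):
            raise ExportError(f"unknown format: {self.format!r}")
        if self.scope not in ("full_table", "selected_targets", "all_targets"):
            raise ExportError(f"unknown scope: {self.scope!r}")

    @property
    def date_str(self) -> str:
        return self.date.isoformat()


def _results_filename(spec: ExportSpec) -> str:
    ext = "csv" if spec.format == "csv" else "txt"
    return f"Query_Results_for_{spec.mirna_label}-{spec.date_str}.{ext}"


def _gene_list_filename(spec: ExportSpec) -> str:
    return f"Target_List_for_{spec.mirna_label}-{spec.date_str}.txt"


def _row_cells(row: ResultRow, sources: Sequence[tuple[str, str]]) -> list[str]:
    cells = [
        row.gene_symbol,
        row.gene_id,
        "|".join(sorted(row.predicted_by)),
    ]
    for source, _ in sources:
        score = row.scores.get(source)
        cells.append("" if score is None else str(score))
    cells.append("|".join(str(p) for p in sorted(row.publications)))
    cells.append(
        "|".join(
            f"{g.go_term}({g.go_ref})"
            for g in sorted(row.go_annotations, key=lambda g: (g.go_term, g.go_ref))
        )
    )
    return cells


def export_results(
    table: ResultTable,
    spec: ExportSpec,
    out_dir,
    sources: Sequence[tuple[str, str]] = DEFAULT_SOURCE_COLUMNS,
) -> Path:
    """Write the result table as CSV or tab-delimited text; returns the path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / _results_filename(spec)
    header = ["candidate_target", "gene_id", "predicted_by"]
    header += [col for _, col in sources]
    header += ["publications", "go_annotations"]
    delimiter = "," if spec.format == "csv" else "\t"
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(
            handle, delimiter=delimiter, lineterminator="\n",
            quoting=csv.QUOTE_MINIMAL,
        )
        writer.writerow(header)
        for row in table.rows:
            writer.writerow(_row_cells(row, sources))
    return path


def export_gene_list(
    table: ResultTable,
    scope: str,
    spec: ExportSpec,
    out_dir,
    selection: Optional[Iterable[str]] = None,
) -> Path:
    """Write one gene symbol per line (deduplicated, table order preserved).

    ``scope='selected_targets'`` keeps only symbols in ``selection`` and
    requires a non-empty selection.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    selected = set(selection) if selection is not None else None
    if scope == "selected_targets":
        if not selected:
            raise ExportError("scope='selected_targets' needs a non-empty selection")
    elif scope not in ("all_targets", "full_table"):
        raise ExportError(f"unknown scope: {scope!r}")
    symbols: list[str] = []
    seen: set[str] = set()
    for row in table.rows:
        if row.gene_symbol in seen:
            continue
        if scope == "selected_targets" and row.gene_symbol not in selected:
            continue
        seen.add(row.gene_symbol)
        symbols.append(row.gene_symbol)
    path = out_dir / _gene_list_filename(spec)
    path.write_text("".join(s + "\n" for s in symbols), encoding="utf-8")
    return path
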