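"""Readers and writers for the pipeline's tabular and network artifacts.

Formats: TSV for tables (6 significant digits for reals), Newick for trees,
GraphML and a Gephi-style CSV edge list for networks. Readers validate and
never silently drop rows or columns; taxonomy lineages are
semicolon-separated with missing ranks rendered ``unclassified_<rank>``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .tables import AsvTable, FormatError, FunctionMatrix, SampleMetadata

logger = logging.getLogger(__name__)

LINEAGE_SEP = ";"
RANKS = ("domain", "phylum", "class", "order", "family", "genus")

__all__ = [
    "read_asv_table", "write_asv_table",
    "read_function_matrix", "write_function_matrix",
    "read_metadata", "write_metadata",
    "write_network", "read_network_graphml",
    "format_lineage", "parse_lineage",
]


def parse_lineage(lineage: str) -> list[str]:
    return [part.strip() for part in lineage.split(LINEAGE_SEP) if part.strip()]


def format_lineage(parts: list[str]) -> str:
    return LINEAGE_SEP.join(parts)


def read_asv_table(path, kingdom: str) -> AsvTable:
    """Read a TSV of ASV counts (first column ASV id, header = sample ids,
    optional trailing ``taxonomy`` column with semicolon-separated lineage)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    taxonomy = None
    if len(df.columns) and df.columns[-1].lower() == "taxonomy":
        tax_col = df.pop(df.columns[-1])
        taxonomy = {asv: parse_lineage(lin) for asv, lin in tax_col.items() if pd.notna(lin)}
    counts = pd.DataFrame(index=df.index, columns=df.columns, dtype=np.int64)
    for col in df.columns:
        for asv, raw in df[col].items():
            try:
                value = int(raw)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path.name}: non-integer count {raw!r} at ASV {asv!r}, sample {col!r}"
                ) from None
            if value < 0:
                raise FormatError(
                    f"{path.name}: negative count {value} at ASV {asv!r}, sample {col!r}"
                )
            counts.at[asv, col] = value
    table = AsvTable(counts=counts, kingdom=kingdom, taxonomy=taxonomy)
    logger.info("read %d ASVs x %d samples (%s) from %s",
                len(table.asv_ids), len(table.sample_ids), kingdom, path)
    return table


def write_asv_table(table: AsvTable, path) -> None:
    df = table.counts.copy()
    if table.taxonomy is not None:
        df["taxonomy"] = [
            format_lineage(table.taxonomy.get(asv, [])) for asv in df.index
        ]
    df.index.name = "asv_id"
    df.to_csv(path, sep="\t")


def read_function_matrix(path, expected_functions=None) -> FunctionMatrix:
    """Read a TSV of soil-function measurements (rows = samples)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].tolist()
        raise FormatError(f"{path.name}: duplicate sample id(s) {dups}")
    if df.isna().any().any():
        arr = df.isna().to_numpy()
        i, j = np.argwhere(arr)[0]
        raise FormatError(
            f"{path.name}: missing value for sample {df.index[i]!r}, "
            f"function {df.columns[j]!r}"
        )
    if expected_functions is not None:
        unknown = [c for c in df.columns if c not in expected_functions]
        if unknown:
            logger.warning("non-canonical function column(s): %s", unknown)
    return FunctionMatrix(values=df)


def write_function_matrix(fm: FunctionMatrix, path, digits: int = 6) -> None:
    out = fm.values.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format=f"%.{digits}g")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={"replicate": int})
    return SampleMetadata(table=df)


def write_metadata(md: SampleMetadata, path) -> None:
    out = md.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def write_network(graph: nx.Graph, path, format: str = "graphml") -> None:
    """Export a co-occurrence network.

    ``graphml`` keeps full double precision with node attribute ``kingdom``
    and edge attributes ``r``, ``p_adj``, ``sign``; ``edge_csv`` writes a
    ``Source,Target,Weight,Sign`` table for spreadsheet/Gephi import.
    """
    path = Path(path)
    if format == "graphml":
        out = graph.copy()
        # GraphML holds scalars only; flatten structured graph attributes
        for key, value in list(out.graph.items()):
            if isinstance(value, dict):
                del out.graph[key]
                for sub, sub_value in value.items():
                    out.graph[f"{key}.{sub}"] = sub_value
        nx.write_graphml(out, path)
    elif format == "edge_csv":
        with open(path, "w") as fh:
            fh.write("Source,Target,Weight,Sign\n")
            for u, v, data in graph.edges(data=True):
                fh.write(f"{u},{v},{data.get('r', 1.0):.6g},{data.get('sign', '+')}\n")
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)
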