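"""Readers and writers for the tabular inputs/outputs and symbol normalization.

All tables are UTF-8 TSV with a header row.  Gene symbols are uppercased,
trimmed and (optionally) alias-resolved through a user-supplied table; no
live HGNC queries are made, for reproducibility.  Floats are written with 6
significant digits.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .model import CellCellEdge, ExpressionAtlas, SchemaError

logger = logging.getLogger(__name__)

#: significant digits for float output in TSV
FLOAT_FMT = "%.6g"

EDGE_COLUMNS = (
    "source_cell",
    "target_cell",
    "ligand",
    "receptor",
    "ligand_tpm",
    "receptor_tpm",
    "weight",
)


def normalize_symbol(
    raw: str,
    alias_table: Optional[Mapping[str, str]] = None,
    return_flag: bool = False,
):
    """Normalize a gene symbol: trim, uppercase, resolve through an alias table.

    When ``return_flag`` is true, returns ``(symbol, unresolved)`` where
    ``unresolved`` is True if an alias table was given but did not contain
    the symbol (the normalized form is then returned unchanged).
    """
    if raw is None or not str(raw).strip():
        raise SchemaError("empty gene symbol")
    sym = str(raw).strip().upper()
    unresolved = False
    if alias_table is not None:
        upper_aliases = {str(k).strip().upper(): str(v).strip().upper() for k, v in alias_table.items()}
        if sym in upper_aliases:
            sym = upper_aliases[sym]
        else:
            unresolved = True
    return (sym, unresolved) if return_flag else sym


def read_expression_atlas(
    path,
    replicate_map: Optional[Mapping[str, str]] = None,
    alias_table: Optional[Mapping[str, str]] = None,
) -> ExpressionAtlas:
    """Read a genes x samples TPM table, collapsing replicates to cell-type means.

    The first column holds gene identifiers; remaining columns are samples
    (or cell types directly when ``replicate_map`` is None).  Replicate
    collapsing is the arithmetic mean of per-sample TPM; a cell type with a
    single library is its own mean.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise SchemaError(f"non-numeric TPM value in {path}: {exc}") from None
    df.index = [normalize_symbol(g, alias_table) for g in df.index]
    dups = df.index[df.index.duplicated()].unique().tolist()
    if dups:
        raise SchemaError(f"duplicate gene symbols after normalization: {dups}")
    vals = df.to_numpy()
    bad = np.argwhere(~np.isfinite(vals) | (vals < 0))
    if bad.size:
        r, c = bad[0]
        raise SchemaError(
            f"negative or non-finite TPM at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if replicate_map is not None:
        missing = sorted(set(df.columns) - set(replicate_map))
        if missing:
            raise SchemaError(f"samples missing from replicate map: {missing}")
        # groupby preserves nothing about sample order: mean is permutation-invariant
        grouped = df.T.groupby(df.columns.map(lambda s: replicate_map[s]).values).mean().T
        return ExpressionAtlas(tpm=grouped, replicate_map=dict(replicate_map))
    return ExpressionAtlas(tpm=df)


def write_expression_atlas(atlas: ExpressionAtlas, path) -> None:
    atlas.tpm.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="gene")


def read_lineage_map(path) -> dict:
    """Read a cell-type -> lineage TSV with columns ``cell_type``, ``lineage``."""
    df = pd.read_csv(path, sep="\t")
    if not {"cell_type", "lineage"}.issubset(df.columns):
        raise SchemaError(f"{path}: lineage map needs columns cell_type, lineage")
    return dict(zip(df["cell_type"], df["lineage"]))


def read_table(path, required: Sequence[str]) -> pd.DataFrame:
    """Read a TSV and check that the required columns are present."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    return df


def _edges_frame(edges: Iterable[CellCellEdge]) -> pd.DataFrame:
    rows = [
        (e.source_cell, e.target_cell, e.ligand, e.receptor, e.ligand_tpm, e.receptor_tpm, e.weight)
        for e in edges
    ]
    return pd.DataFrame(rows, columns=list(EDGE_COLUMNS))


def write_edge_list(edges: Sequence[CellCellEdge], path, fmt: str = "tsv") -> None:
    """Write a cell-cell edge list as TSV, GraphML or JSON.

    TSV carries exactly the 7 documented columns.  GraphML nodes are cell
    types and each edge carries ligand/receptor/TPM/weight attributes (edges
    are keyed so parallel pair-edges between the same two cells survive).
    JSON is the hive-view schema: ``{"nodes": [...], "edges": [...]}``.
    """
    path = Path(path)
    if fmt == "tsv":
        _edges_frame(edges).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    elif fmt == "graphml":
        g = nx.MultiDiGraph()
        for e in edges:
            g.add_node(e.source_cell)
            g.add_node(e.target_cell)
            g.add_edge(
                e.source_cell,
                e.target_cell,
                ligand=e.ligand,
                receptor=e.receptor,
                ligand_tpm=float(e.ligand_tpm),
                receptor_tpm=float(e.receptor_tpm),
                weight=float(e.weight),
            )
        nx.write_graphml(g, path)
    elif fmt == "json":
        nodes = sorted({e.source_cell for e in edges} | {e.target_cell for e in edges})
        payload = {
            "nodes": [{"id": n} for n in nodes],
            "edges": [
                {
                    "source": e.source_cell,
                    "target": e.target_cell,
                    "ligand": e.ligand,
                    "receptor": e.receptor,
                    "ligand_tpm": e.ligand_tpm,
                    "receptor_tpm": e.receptor_tpm,
                    "weight": e.weight,
                }
                for e in edges
            ],
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise SchemaError(f"unknown edge-list format {fmt!r}; expected tsv, graphml or json")


def read_edge_list(path, fmt: str = "tsv") -> list:
    """Re-read an edge list written by :func:`write_edge_list`."""
    path = Path(path)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t")
        return [CellCellEdge(*row) for row in df[list(EDGE_COLUMNS)].itertuples(index=False)]
    if fmt == "graphml":
        g = nx.read_graphml(path, force_multigraph=True)
        return [
            CellCellEdge(
                source_cell=u,
                target_cell=v,
                ligand=d["ligand"],
                receptor=d["receptor"],
                ligand_tpm=d["ligand_tpm"],
                receptor_tpm=d["receptor_tpm"],
                weight=d["weight"],
            )
            for u, v, d in g.edges(data=True)
        ]
    if fmt == "json":
        payload = json.loads(Path(path).read_text())
        return [
            CellCellEdge(
                source_cell=d["source"],
                target_cell=d["target"],
                ligand=d["ligand"],
                receptor=d["receptor"],
                ligand_tpm=d["ligand_tpm"],
                receptor_tpm=d["receptor_tpm"],
                weight=d["weight"],
            )
            for d in payload["edges"]
        ]
    raise SchemaError(f"unknown edge-list format {fmt!r}")
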