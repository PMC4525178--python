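"""Shared data model: expression atlas, gene metadata, lineages, network edges."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

#: The six broad cell-type lineage classes used throughout.
LINEAGES = (
    "endothelial",
    "epithelial",
    "haematopoietic",
    "mesenchymal",
    "nervous",
    "other",
)


class SchemaError(ValueError):
    """An input table violates the documented schema."""


@dataclass
class ExpressionAtlas:
    """Gene-level TPM expression across a panel of primary cell types.

    ``tpm`` is a genes x cell-types DataFrame of non-negative, finite TPM
    values.  When the atlas was built from per-sample libraries,
    ``replicate_map`` records which sample collapsed into which cell type;
    each cell-type column is then the arithmetic mean of its replicates.
    """

    tpm: pd.DataFrame
    replicate_map: Optional[Mapping[str, str]] = None

    def __post_init__(self) -> None:
        values = self.tpm.to_numpy(dtype=float)
        if values.size and (not np.isfinite(values).all() or (values < 0).any()):
            bad = np.argwhere(~np.isfinite(values) | (values < 0))
            r, c = bad[0]
            raise SchemaError(
                f"non-finite or negative TPM at gene {self.tpm.index[r]!r}, "
                f"cell {self.tpm.columns[c]!r}"
            )
        dup_genes = self.tpm.index[self.tpm.index.duplicated()].unique().tolist()
        if dup_genes:
            raise SchemaError(f"duplicate gene symbols after normalization: {dup_genes}")
        dup_cells = self.tpm.columns[self.tpm.columns.duplicated()].unique().tolist()
        if dup_cells:
            raise SchemaError(f"duplicate cell-type names: {dup_cells}")

    @property
    def genes(self) -> list:
        return list(self.tpm.index)

    @property
    def cell_types(self) -> list:
        return list(self.tpm.columns)

    @property
    def n_genes(self) -> int:
        return self.tpm.shape[0]

    @property
    def n_cells(self) -> int:
        return self.tpm.shape[1]


@dataclass
class GeneRecord:
    """Per-gene metadata: identifiers, protein length, evolutionary age.

    ``phylostratum`` is an integer rank on the age table's scale; by
    convention here a *larger* rank means a more recent origin.
    """

    symbol: str
    uniprot_id: Optional[str] = None
    length_aa: Optional[int] = None
    age_mya: Optional[float] = None
    phylostratum: Optional[int] = None

    def __post_init__(self) -> None:
        if self.length_aa is not None and self.length_aa < 1:
            raise SchemaError(f"{self.symbol}: length_aa must be >= 1")
        if self.age_mya is not None and self.age_mya < 0:
            raise SchemaError(f"{self.symbol}: age_mya must be >= 0")


@dataclass(frozen=True)
class CellCellEdge:
    """A directed signalling edge: ligand from one cell type to a receptor on another.

    The weight is the product of ligand and receptor TPM, the edge-ranking
    statistic used for top-path filtering.
    """

    source_cell: str
    target_cell: str
    ligand: str
    receptor: str
    ligand_tpm: float
    receptor_tpm: float
    weight: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.weight is None:
            object.__setattr__(self, "weight", self.ligand_tpm * self.receptor_tpm)


def validate_lineage_map(mapping: Mapping[str, str], cell_types) -> dict:
    """Check that every cell type maps to exactly one known lineage.

    Unmapped cell types are a hard error: lineage statistics silently
    computed on a partial panel would be biased.
    """
    unknown = sorted(set(mapping.values()) - set(LINEAGES))
    if unknown:
        raise SchemaError(f"unknown lineage labels: {unknown}; expected one of {LINEAGES}")
    missing = sorted(set(cell_types) - set(mapping))
    if missing:
        raise SchemaError(f"cell types missing from lineage map: {missing}")
    return {c: mapping[c] for c in cell_types}
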