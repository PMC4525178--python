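"""Thresholded cell-to-cell communication networks from a TPM atlas.

A gene is "detected" in a cell type when its TPM is at or above a detection
threshold (10 TPM by default, with 50 and 100 as the other standard
presets).  From the detection matrix and a ligand-receptor pair set this
module derives per-cell repertoires, autocrine fractions, specific/broad
expression quadrants, cell x cell path-count matrices, and explicit
weighted edge lists where the edge weight is ligand TPM x receptor TPM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Set

import numpy as np
import pandas as pd

from .model import CellCellEdge, ExpressionAtlas, SchemaError
from .pairs import PairRecord, PairSet

logger = logging.getLogger(__name__)

THRESHOLD_PRESETS = (10.0, 50.0, 100.0)


@dataclass
class DetectionMatrix:
    """Boolean genes x cell-types matrix: TPM at-or-above the threshold."""

    det: pd.DataFrame
    threshold_tpm: float

    @property
    def genes(self) -> list:
        return list(self.det.index)

    @property
    def cell_types(self) -> list:
        return list(self.det.columns)

    def detected_cells(self, gene: str) -> Set[str]:
        """Cells detecting ``gene``; genes absent from the atlas are never detected."""
        if gene not in self.det.index:
            return set()
        row = self.det.loc[gene]
        return set(row.index[row])

    def breadth(self, gene: str) -> int:
        return len(self.detected_cells(gene))


def detect(atlas: ExpressionAtlas, threshold: float, op: str = ">=") -> DetectionMatrix:
    """Threshold the atlas into a boolean detection matrix.

    The comparison operator defaults to ``>=`` (a value exactly at the
    threshold counts as detected); ``>`` is available for strict use.
    """
    if threshold <= 0:
        raise SchemaError("detection threshold must be > 0")
    if op == ">=":
        det = atlas.tpm >= threshold
    elif op == ">":
        det = atlas.tpm > threshold
    else:
        raise SchemaError(f"unknown comparison operator {op!r}")
    return DetectionMatrix(det=det, threshold_tpm=float(threshold))


def _active(pairs) -> List[PairRecord]:
    return pairs.active() if isinstance(pairs, PairSet) else list(pairs)


def expressed_pairs(pairs, det: DetectionMatrix) -> List[PairRecord]:
    """Pairs whose ligand and receptor are each detected in at least one cell
    (not necessarily the same cell)."""
    out = []
    for rec in _active(pairs):
        if det.detected_cells(rec.ligand) and det.detected_cells(rec.receptor):
            out.append(rec)
    return out


def repertoire_counts(det: DetectionMatrix, pairs) -> pd.DataFrame:
    """Per cell type, the number of distinct ligand and receptor genes detected."""
    active = _active(pairs)
    ligands = sorted({r.ligand for r in active})
    receptors = sorted({r.receptor for r in active})
    rows = []
    for cell in det.cell_types:
        n_lig = sum(1 for g in ligands if cell in det.detected_cells(g))
        n_rec = sum(1 for g in receptors if cell in det.detected_cells(g))
        rows.append((cell, n_lig, n_rec))
    return pd.DataFrame(rows, columns=["cell_type", "n_ligands", "n_receptors"]).set_index(
        "cell_type"
    )


def autocrine_fractions(det: DetectionMatrix, pairs) -> pd.DataFrame:
    """Per cell, the fraction of its expressed ligands (receptors) whose
    cognate partner is also detected on the same cell; NaN when the cell
    expresses no ligand (receptor)."""
    active = _active(pairs)
    lig_partners: dict = {}
    rec_partners: dict = {}
    for r in active:
        lig_partners.setdefault(r.ligand, set()).add(r.receptor)
        rec_partners.setdefault(r.receptor, set()).add(r.ligand)
    rows = []
    for cell in det.cell_types:
        expressed_lig = [g for g in lig_partners if cell in det.detected_cells(g)]
        expressed_rec = [g for g in rec_partners if cell in det.detected_cells(g)]
        lf = (
            sum(
                1
                for g in expressed_lig
                if any(cell in det.detected_cells(p) for p in lig_partners[g])
            )
            / len(expressed_lig)
            if expressed_lig
            else np.nan
        )
        rf = (
            sum(
                1
                for g in expressed_rec
                if any(cell in det.detected_cells(p) for p in rec_partners[g])
            )
            / len(expressed_rec)
            if expressed_rec
            else np.nan
        )
        rows.append((cell, lf, rf))
    return pd.DataFrame(
        rows, columns=["cell_type", "ligand_fraction", "receptor_fraction"]
    ).set_index("cell_type")


@dataclass
class QuadrantReport:
    """Breadths, medians, per-pair quadrant labels and quadrant fractions."""

    ligand_breadth: dict
    receptor_breadth: dict
    ligand_median: float
    receptor_median: float
    pair_quadrant: dict  # (ligand, receptor) -> e.g. "specific/broad"
    fractions: dict  # quadrant label -> fraction; sums to 1 when pairs exist


def breadth_and_quadrants(det: DetectionMatrix, pairs) -> QuadrantReport:
    """Median-split genes into specific vs broad and classify each pair.

    Breadth is the number of cell types detecting the gene.  The ligand and
    receptor medians are taken over the distinct genes participating in the
    given pairs, per role.  A gene is "specific" iff its breadth is at or
    below its role's median (the tie rule keeps the median gene specific).
    """
    active = _active(pairs)
    ligands = sorted({r.ligand for r in active})
    receptors = sorted({r.receptor for r in active})
    lb = {g: det.breadth(g) for g in ligands}
    rb = {g: det.breadth(g) for g in receptors}
    lmed = float(np.median(list(lb.values()))) if lb else np.nan
    rmed = float(np.median(list(rb.values()))) if rb else np.nan
    quadrants: dict = {}
    counts = {
        "specific/specific": 0,
        "specific/broad": 0,
        "broad/specific": 0,
        "broad/broad": 0,
    }
    for r in active:
        lig_spec = "specific" if lb[r.ligand] <= lmed else "broad"
        rec_spec = "specific" if rb[r.receptor] <= rmed else "broad"
        label = f"{lig_spec}/{rec_spec}"
        quadrants[r.key] = label
        counts[label] += 1
    n = len(active)
    fractions = {k: (v / n if n else 0.0) for k, v in counts.items()}
    return QuadrantReport(lb, rb, lmed, rmed, quadrants, fractions)


def path_count_matrix(det: DetectionMatrix, pairs) -> pd.DataFrame:
    """Cell x cell matrix of available signalling paths.

    Entry (A, B) counts pairs whose ligand is detected in A and receptor in
    B, over all ordered cell pairs including the diagonal (autocrine paths).
    """
    cells = det.cell_types
    mat = np.zeros((len(cells), len(cells)), dtype=int)
    idx = {c: i for i, c in enumerate(cells)}
    for r in _active(pairs):
        lig_cells = det.detected_cells(r.ligand)
        rec_cells = det.detected_cells(r.receptor)
        for a in lig_cells:
            ia = idx[a]
            for b in rec_cells:
                mat[ia, idx[b]] += 1
    return pd.DataFrame(mat, index=cells, columns=cells)


def build_edges(
    atlas: ExpressionAtlas,
    pairs,
    threshold: float,
    top_n: Optional[int] = None,
    include_self: bool = True,
    op: str = ">=",
) -> List[CellCellEdge]:
    """Enumerate weighted edges for every (pair, source cell, target cell)
    with both partners at or above the threshold in their respective cells.

    Edges are ranked by weight (ligand TPM x receptor TPM); ``top_n`` keeps
    the heaviest edges with deterministic lexicographic tie-breaking on
    (ligand, receptor, source cell, target cell).  Autocrine self-edges are
    genuine edges and included unless ``include_self`` is False.
    """
    det = detect(atlas, threshold, op=op)
    edges: List[CellCellEdge] = []
    missing = set()
    for r in _active(pairs):
        for g in (r.ligand, r.receptor):
            if g not in atlas.tpm.index:
                missing.add(g)
        lig_cells = det.detected_cells(r.ligand)
        rec_cells = det.detected_cells(r.receptor)
        for a in sorted(lig_cells):
            lig_tpm = float(atlas.tpm.at[r.ligand, a])
            for b in sorted(rec_cells):
                if not include_self and a == b:
                    continue
                rec_tpm = float(atlas.tpm.at[r.receptor, b])
                edges.append(
                    CellCellEdge(
                        source_cell=a,
                        target_cell=b,
                        ligand=r.ligand,
                        receptor=r.receptor,
                        ligand_tpm=lig_tpm,
                        receptor_tpm=rec_tpm,
                    )
                )
    if missing:
        logger.warning("%d pair genes absent from atlas, treated as never detected", len(missing))
    edges.sort(key=lambda e: (-e.weight, e.ligand, e.receptor, e.source_cell, e.target_cell))
    if top_n is not None:
        edges = edges[: int(top_n)]
    return edges


@dataclass
class ConcordanceResult:
    """Detection vs proteome/literature concordance fractions."""

    supported_fraction: float  # detected genes with proteome or literature support
    n_detected: int
    n_supported: int
    proteome_only_array_fraction: Optional[float] = None  # candidate false positives
    detected_array_fraction: Optional[float] = None  # detected-set array support


def detection_concordance(
    detected: Set[str],
    proteome: Set[str],
    literature: Set[str],
    array_detected: Optional[Set[str]] = None,
    probed: Optional[Set[str]] = None,
) -> ConcordanceResult:
    """Concordance arithmetic between threshold-detected genes and protein evidence.

    ``supported_fraction`` is |detected ∩ (proteome ∪ literature)| / |detected|.
    When an array data set is given (``array_detected`` within the universe
    of ``probed`` genes carrying unique probes), two further fractions are
    computed: among proteome-only genes with probes, the fraction with
    detectable transcripts on the array (an upper bound on transcriptomic
    false negatives), and the same fraction among the detected genes
    (a positive control).
    """
    if not detected:
        raise SchemaError("detection_concordance: empty detected set")
    support = proteome | literature
    n_supported = len(detected & support)
    res = ConcordanceResult(
        supported_fraction=n_supported / len(detected),
        n_detected=len(detected),
        n_supported=n_supported,
    )
    if array_detected is not None:
        universe = probed if probed is not None else (detected | proteome | array_detected)
        proteome_only = (proteome - detected) & universe
        detected_probed = detected & universe
        if proteome_only:
            res.proteome_only_array_fraction = len(proteome_only & array_detected) / len(
                proteome_only
            )
        if detected_probed:
            res.detected_array_fraction = len(detected_probed & array_detected) / len(
                detected_probed
            )
    return res
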