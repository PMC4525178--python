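"""Major-signalling pairs and lineage-level enrichment statistics.

For every expressed ligand-receptor pair the cell type with the highest
ligand TPM is the major transmitter and the cell with the highest receptor
TPM the major receiver.  Tallying these over six broad lineages gives a
6 x 6 lineage matrix.  Two exact binomial test families ask (a) whether a
lineage hosts more/fewer maximal ligands or receptors than its share of
cell types predicts, and (b) whether particular lineage-to-lineage paths
are over-represented relative to the product of the max-transmitter and
max-receiver marginals.  P values are Benjamini-Hochberg adjusted within
each family.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

from .model import LINEAGES, ExpressionAtlas, SchemaError
from .network import _active

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MajorSignallingPair:
    ligand: str
    receptor: str
    max_transmitter: str
    max_receiver: str
    ligand_tpm: float
    receptor_tpm: float


def major_pairs(atlas: ExpressionAtlas, pairs) -> List[MajorSignallingPair]:
    """Argmax cells per pair; ties broken by lexicographically smallest cell name.

    Pairs whose ligand or receptor has all-zero expression (or is absent from
    the atlas) carry no defined maximum and are excluded with a warning.
    """
    out = []
    n_skipped = 0
    for rec in _active(pairs):
        cells = []
        tpms = []
        ok = True
        for gene in (rec.ligand, rec.receptor):
            if gene not in atlas.tpm.index:
                ok = False
                break
            row = atlas.tpm.loc[gene]
            peak = float(row.max())
            if peak <= 0:
                ok = False
                break
            argmax_cells = sorted(row.index[row == peak])
            cells.append(argmax_cells[0])
            tpms.append(peak)
        if not ok:
            n_skipped += 1
            continue
        out.append(
            MajorSignallingPair(
                ligand=rec.ligand,
                receptor=rec.receptor,
                max_transmitter=cells[0],
                max_receiver=cells[1],
                ligand_tpm=tpms[0],
                receptor_tpm=tpms[1],
            )
        )
    if n_skipped:
        logger.warning("major_pairs: %d pairs skipped (all-zero or missing gene)", n_skipped)
    return out


def lineage_matrix(
    mp: Sequence[MajorSignallingPair], lineage_map: Mapping[str, str]
) -> pd.DataFrame:
    """6 x 6 counts of major-signalling pairs by (transmitter lineage, receiver lineage)."""
    mat = pd.DataFrame(0, index=list(LINEAGES), columns=list(LINEAGES), dtype=int)
    for p in mp:
        for cell in (p.max_transmitter, p.max_receiver):
            if cell not in lineage_map:
                raise SchemaError(f"cell type {cell!r} missing from lineage map")
        mat.at[lineage_map[p.max_transmitter], lineage_map[p.max_receiver]] += 1
    return mat


def _bh(frame: pd.DataFrame) -> pd.DataFrame:
    if len(frame):
        frame["q"] = multipletests(frame["p"].to_numpy(), method="fdr_bh")[1]
    else:
        frame["q"] = []
    return frame


def lineage_representation_test(
    mp: Sequence[MajorSignallingPair],
    lineage_map: Mapping[str, str],
    n_cells_per_lineage: Mapping[str, int],
) -> pd.DataFrame:
    """Is a lineage over/under-represented among max-transmitters or max-receivers?

    For each lineage and role, x counts pairs whose maximal cell lies in the
    lineage, n is the number of pairs, and the null success probability is
    the lineage's share of cell types.  Two-sided exact binomial tests, BH
    adjusted across the 12 (lineage, role) tests; direction reports which
    side of the expectation the observation falls on.
    """
    total_cells = sum(n_cells_per_lineage.get(l, 0) for l in LINEAGES)
    if total_cells <= 0:
        raise SchemaError("total cell count must be > 0")
    n = len(mp)
    tallies = {
        "ligand": Counter(lineage_map[p.max_transmitter] for p in mp),
        "receptor": Counter(lineage_map[p.max_receiver] for p in mp),
    }
    rows = []
    for lineage in LINEAGES:
        p0 = n_cells_per_lineage.get(lineage, 0) / total_cells
        for role in ("ligand", "receptor"):
            x = tallies[role][lineage]
            if n == 0:
                pval = 1.0
            elif p0 == 0.0:
                pval = 1.0 if x == 0 else 0.0
            elif p0 == 1.0:
                pval = 1.0 if x == n else 0.0
            else:
                pval = binomtest(x, n, p0, alternative="two-sided").pvalue
            direction = "over" if (n and x / n > p0) else ("under" if (n and x / n < p0) else "none")
            rows.append((lineage, role, x, n, p0, pval, direction))
    df = pd.DataFrame(rows, columns=["lineage", "role", "x", "n", "p0", "p", "direction"])
    return _bh(df)


def path_bias_test(
    lmtx: pd.DataFrame,
    method: str = "binomial",
    n_permutations: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Are lineage-A -> lineage-B paths more common than the marginals predict?

    The null probability for cell (A, B) is the product of the
    max-transmitter marginal for A and the max-receiver marginal for B,
    deliberately ignoring how many cell types each lineage contains.  Exact
    two-sided binomial tests, BH adjusted across the 36 ordered lineage
    pairs.  ``method="permutation"`` instead permutes receiver assignments
    against transmitters and reports empirical two-sided p values.
    """
    n = int(lmtx.to_numpy().sum())
    if n < 1:
        raise SchemaError("lineage matrix total must be >= 1")
    row_marg = lmtx.sum(axis=1) / n
    col_marg = lmtx.sum(axis=0) / n
    rows = []
    if method == "permutation":
        if rng is None:
            rng = np.random.default_rng(0)
        transmitters = np.repeat(np.arange(len(lmtx.index)), lmtx.sum(axis=1).to_numpy())
        receivers = np.repeat(np.arange(len(lmtx.columns)), lmtx.sum(axis=0).to_numpy())
        perm_counts = np.zeros((n_permutations, len(lmtx.index), len(lmtx.columns)), dtype=int)
        for it in range(n_permutations):
            perm = rng.permutation(receivers)
            np.add.at(perm_counts[it], (transmitters, perm), 1)
    for i, a in enumerate(lmtx.index):
        for j, b in enumerate(lmtx.columns):
            x = int(lmtx.at[a, b])
            p0 = float(row_marg[a] * col_marg[b])
            if p0 == 0.0:
                if x > 0:
                    raise SchemaError(f"degenerate marginal: p0=0 but count({a},{b})={x}")
                pval = 1.0
            elif method == "binomial":
                pval = binomtest(x, n, p0, alternative="two-sided").pvalue
            elif method == "permutation":
                null = perm_counts[:, i, j]
                dev = np.abs(null - n * p0)
                pval = float((np.sum(dev >= abs(x - n * p0)) + 1) / (n_permutations + 1))
            else:
                raise SchemaError(f"unknown path_bias_test method {method!r}")
            direction = "over" if x / n > p0 else ("under" if x / n < p0 else "none")
            rows.append((a, b, x, n, p0, pval, direction))
    df = pd.DataFrame(
        rows, columns=["from_lineage", "to_lineage", "x", "n", "p0", "p", "direction"]
    )
    return _bh(df)


def export_lineage_gene_lists(
    mp: Sequence[MajorSignallingPair],
    lineage_map: Mapping[str, str],
    lineage_a: str,
    lineage_b: str,
) -> Tuple[List[str], List[str]]:
    """Foreground/background gene lists for external enrichment tools.

    Foreground: ligands and receptors of pairs on the A -> B lineage edge.
    Background: all ligands and receptors across the major-signalling pairs.
    """
    fg, bg = set(), set()
    for p in mp:
        bg.update((p.ligand, p.receptor))
        if lineage_map[p.max_transmitter] == lineage_a and lineage_map[p.max_receiver] == lineage_b:
            fg.update((p.ligand, p.receptor))
    return sorted(fg), sorted(bg)


def write_major_pairs(mp: Sequence[MajorSignallingPair], path) -> None:
    pd.DataFrame(
        [
            (p.ligand, p.receptor, p.max_transmitter, p.max_receiver, p.ligand_tpm, p.receptor_tpm)
            for p in mp
        ],
        columns=[
            "ligand",
            "receptor",
            "max_transmitter",
            "max_receiver",
            "ligand_tpm",
            "receptor_tpm",
        ],
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
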