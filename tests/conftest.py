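import numpy as np
import pandas as pd
import pytest

from lrnet.model import ExpressionAtlas, LINEAGES
from lrnet.pairs import PairRecord, PairSet


def random_instance(rng, n_genes=None, n_cells=None, n_pairs=None):
    """A small random atlas + pair set for oracle-equivalence checks."""
    n_genes = n_genes or int(rng.integers(4, 21))
    n_cells = n_cells or int(rng.integers(2, 7))
    genes = [f"G{i}" for i in range(n_genes)]
    cells = [f"C{i}" for i in range(n_cells)]
    tpm = rng.lognormal(2.0, 1.5, size=(n_genes, n_cells))
    tpm[rng.random(tpm.shape) < 0.3] = 0.0
    atlas = ExpressionAtlas(tpm=pd.DataFrame(tpm, index=genes, columns=cells))
    n_pairs = n_pairs or int(rng.integers(1, 2 * n_genes))
    ps = PairSet()
    for _ in range(n_pairs):
        lig, rec = rng.choice(genes, size=2, replace=False)
        ps.add(PairRecord(ligand=str(lig), receptor=str(rec)))
    return atlas, ps


@pytest.fixture
def small_atlas():
    tpm = pd.DataFrame(
        {
            "cellA": [12.0, 0.0, 55.0, 9.9],
            "cellB": [10.0, 3.0, 120.0, 0.0],
            "cellC": [0.0, 30.0, 8.0, 101.0],
        },
        index=["L1", "L2", "R1", "R2"],
    )
    return ExpressionAtlas(tpm=tpm)


@pytest.fixture
def small_pairs():
    ps = PairSet()
    ps.add(PairRecord(ligand="L1", receptor="R1", pmids={"1"}, status="reference"))
    ps.add(PairRecord(ligand="L2", receptor="R2"))
    return ps


@pytest.fixture
def lineage_map_24():
    lmap = {}
    for lineage in LINEAGES:
        for i in range(4):
            lmap[f"{lineage}_{i}"] = lineage
    return lmap
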