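"""Thresholded network construction against brute-force enumeration oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from lrnet.model import ExpressionAtlas, SchemaError
from lrnet.network import (
    autocrine_fractions,
    breadth_and_quadrants,
    build_edges,
    detect,
    detection_concordance,
    expressed_pairs,
    path_count_matrix,
    repertoire_counts,
)
from lrnet.pairs import PairRecord, PairSet

from conftest import random_instance


# -- brute-force oracles ----------------------------------------------------

def oracle_detected(atlas, threshold):
    return {
        (g, c)
        for g in atlas.genes
        for c in atlas.cell_types
        if atlas.tpm.at[g, c] >= threshold
    }


def oracle_expressed_pairs(atlas, ps, threshold):
    det = oracle_detected(atlas, threshold)
    out = []
    for rec in ps.active():
        lig_ok = any((rec.ligand, c) in det for c in atlas.cell_types)
        rec_ok = any((rec.receptor, c) in det for c in atlas.cell_types)
        if lig_ok and rec_ok:
            out.append(rec.key)
    return sorted(out)


def oracle_path_counts(atlas, ps, threshold):
    det = oracle_detected(atlas, threshold)
    counts = {}
    for a in atlas.cell_types:
        for b in atlas.cell_types:
            counts[(a, b)] = sum(
                1
                for rec in ps.active()
                if (rec.ligand, a) in det and (rec.receptor, b) in det
            )
    return counts


class TestDetect:
    def test_all_zero_atlas_detects_nothing(self):
        atlas = ExpressionAtlas(tpm=pd.DataFrame(np.zeros((3, 2)),
                                                 index=list("abc"), columns=["x", "y"]))
        assert not detect(atlas, 10).det.to_numpy().any()

    def test_value_exactly_at_threshold_is_detected(self):
        atlas = ExpressionAtlas(tpm=pd.DataFrame({"c": [10.0]}, index=["g"]))
        assert detect(atlas, 10).det.at["g", "c"]
        assert not detect(atlas, 10, op=">").det.at["g", "c"]

    def test_nonpositive_threshold_errors(self):
        atlas = ExpressionAtlas(tpm=pd.DataFrame({"c": [1.0]}, index=["g"]))
        with pytest.raises(SchemaError):
            detect(atlas, 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_detected_count_monotone_in_threshold(self, seed):
        atlas, _ = random_instance(np.random.default_rng(seed))
        n10 = int(detect(atlas, 10).det.to_numpy().sum())
        n50 = int(detect(atlas, 50).det.to_numpy().sum())
        n100 = int(detect(atlas, 100).det.to_numpy().sum())
        assert n10 >= n50 >= n100


class TestOracleEquivalence:
    """Every set/count operation equals brute-force enumeration on small instances."""

    @pytest.mark.parametrize("seed", range(10))
    def test_expressed_pairs(self, seed):
        atlas, ps = random_instance(np.random.default_rng(seed))
        det = detect(atlas, 10)
        got = sorted(r.key for r in expressed_pairs(ps, det))
        assert got == oracle_expressed_pairs(atlas, ps, 10)

    @pytest.mark.parametrize("seed", range(10))
    def test_repertoire_counts(self, seed):
        atlas, ps = random_instance(np.random.default_rng(100 + seed))
        det = detect(atlas, 10)
        reps = repertoire_counts(det, ps)
        oracle = oracle_detected(atlas, 10)
        ligs = {r.ligand for r in ps.active()}
        recs = {r.receptor for r in ps.active()}
        for cell in atlas.cell_types:
            assert reps.at[cell, "n_ligands"] == sum(1 for g in ligs if (g, cell) in oracle)
            assert reps.at[cell, "n_receptors"] == sum(1 for g in recs if (g, cell) in oracle)

    @pytest.mark.parametrize("seed", range(10))
    def test_autocrine_fractions(self, seed):
        atlas, ps = random_instance(np.random.default_rng(200 + seed))
        det = detect(atlas, 10)
        frac = autocrine_fractions(det, ps)
        oracle = oracle_detected(atlas, 10)
        for cell in atlas.cell_types:
            ligs = {r.ligand for r in ps.active() if (r.ligand, cell) in oracle}
            num = sum(
                1
                for g in ligs
                if any(
                    (r.receptor, cell) in oracle for r in ps.active() if r.ligand == g
                )
            )
            expected = num / len(ligs) if ligs else float("nan")
            got = frac.at[cell, "ligand_fraction"]
            assert (math.isnan(expected) and math.isnan(got)) or got == expected

    @pytest.mark.parametrize("seed", range(10))
    def test_path_count_matrix(self, seed):
        atlas, ps = random_instance(np.random.default_rng(300 + seed))
        det = detect(atlas, 10)
        mat = path_count_matrix(det, ps)
        oracle = oracle_path_counts(atlas, ps, 10)
        for (a, b), v in oracle.items():
            assert mat.at[a, b] == v

    @pytest.mark.parametrize("seed", range(5))
    def test_diagonal_equals_autocrine_pair_count(self, seed):
        # path_count (A, A) is by definition the number of pairs fully
        # available on cell A, the numerator universe of autocrine signalling
        atlas, ps = random_instance(np.random.default_rng(400 + seed))
        det = detect(atlas, 10)
        mat = path_count_matrix(det, ps)
        for cell in atlas.cell_types:
            n_auto = sum(
                1
                for r in ps.active()
                if cell in det.detected_cells(r.ligand)
                and cell in det.detected_cells(r.receptor)
            )
            assert mat.at[cell, cell] == n_auto


class TestAutocrineEdgeCases:
    def test_cell_expressing_both_partners_scores_one(self):
        atlas = ExpressionAtlas(tpm=pd.DataFrame({"c": [20.0, 30.0]}, index=["L", "R"]))
        ps = PairSet([PairRecord("L", "R")])
        frac = autocrine_fractions(detect(atlas, 10), ps)
        assert frac.at["c", "ligand_fraction"] == 1.0
        assert frac.at["c", "receptor_fraction"] == 1.0

    def test_ligand_without_receptor_zero_and_missing(self):
        atlas = ExpressionAtlas(tpm=pd.DataFrame({"c": [20.0, 0.0]}, index=["L", "R"]))
        ps = PairSet([PairRecord("L", "R")])
        frac = autocrine_fractions(detect(atlas, 10), ps)
        assert frac.at["c", "ligand_fraction"] == 0.0
        assert math.isnan(frac.at["c", "receptor_fraction"])


class TestQuadrants:
    def test_median_split_two_ligands(self):
        # ligand breadths 1 and 5 -> median 3: breadth-1 specific, breadth-5 broad
        cells = [f"c{i}" for i in range(5)]
        tpm = pd.DataFrame(0.0, index=["L1", "L2", "R1"], columns=cells)
        tpm.loc["L1", "c0"] = 20.0
        tpm.loc["L2"] = 20.0
        tpm.loc["R1", "c0"] = 20.0
        atlas = ExpressionAtlas(tpm=tpm)
        ps = PairSet([PairRecord("L1", "R1"), PairRecord("L2", "R1")])
        det = detect(atlas, 10)
        rep = breadth_and_quadrants(det, expressed_pairs(ps, det))
        assert rep.ligand_median == 3
        assert rep.pair_quadrant[("L1", "R1")].startswith("specific")
        assert rep.pair_quadrant[("L2", "R1")].startswith("broad")

    def test_all_equal_breadths_classified_specific(self):
        cells = ["c0", "c1"]
        tpm = pd.DataFrame(20.0, index=["L1", "L2", "R1", "R2"], columns=cells)
        atlas = ExpressionAtlas(tpm=tpm)
        ps = PairSet([PairRecord("L1", "R1"), PairRecord("L2", "R2")])
        det = detect(atlas, 10)
        rep = breadth_and_quadrants(det, expressed_pairs(ps, det))
        assert all(q == "specific/specific" for q in rep.pair_quadrant.values())

    @pytest.mark.parametrize("seed", range(5))
    def test_quadrant_fractions_sum_to_one(self, seed):
        atlas, ps = random_instance(np.random.default_rng(500 + seed))
        det = detect(atlas, 5)
        expr = expressed_pairs(ps, det)
        if not expr:
            pytest.skip("no expressed pairs in this draw")
        rep = breadth_and_quadrants(det, expr)
        assert math.isclose(sum(rep.fractions.values()), 1.0)


class TestBuildEdges:
    def _csf_atlas(self):
        cells = ["mast cell, stimulated", "CD14+ endothelial progenitor", "other cell"]
        tpm = pd.DataFrame(
            {
                cells[0]: [1109.0, 15.0],
                cells[1]: [12.0, 699.0],
                cells[2]: [50.0, 40.0],
            },
            index=["CSF1", "CSF1R"],
        )
        return ExpressionAtlas(tpm=tpm)

    def test_top_edge_is_highest_expressor_pair(self):
        atlas = self._csf_atlas()
        ps = PairSet([PairRecord("CSF1", "CSF1R")])
        edges = build_edges(atlas, ps, threshold=10, top_n=1)
        (e,) = edges
        assert e.source_cell == "mast cell, stimulated"
        assert e.target_cell == "CD14+ endothelial progenitor"
        assert e.weight == 1109.0 * 699.0 == 775191.0

    def test_weight_is_exact_product_bit_level(self):
        atlas = self._csf_atlas()
        ps = PairSet([PairRecord("CSF1", "CSF1R")])
        for e in build_edges(atlas, ps, threshold=10):
            assert e.weight == e.ligand_tpm * e.receptor_tpm

    def test_threshold_above_max_gives_empty_list(self):
        atlas = self._csf_atlas()
        ps = PairSet([PairRecord("CSF1", "CSF1R")])
        assert build_edges(atlas, ps, threshold=2000) == []

    def test_self_edges_included_by_default_excludable(self):
        atlas = ExpressionAtlas(tpm=pd.DataFrame({"c": [20.0, 30.0]}, index=["L", "R"]))
        ps = PairSet([PairRecord("L", "R")])
        assert len(build_edges(atlas, ps, 10)) == 1
        assert build_edges(atlas, ps, 10, include_self=False) == []

    def test_pair_gene_missing_from_atlas_never_detected(self):
        atlas = ExpressionAtlas(tpm=pd.DataFrame({"c": [20.0]}, index=["L"]))
        ps = PairSet([PairRecord("L", "ABSENT")])
        assert build_edges(atlas, ps, 10) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_edge_counts_monotone_in_threshold(self, seed):
        atlas, ps = random_instance(np.random.default_rng(600 + seed))
        n = [len(build_edges(atlas, ps, t)) for t in (10, 50, 100)]
        assert n[0] >= n[1] >= n[2]


class TestConcordance:
    def test_bcell_style_arithmetic(self):
        detected = {f"D{i}" for i in range(179)}
        supported = {f"D{i}" for i in range(147)}  # proteome or literature
        res = detection_concordance(detected, supported, set())
        assert res.n_detected == 179 and res.n_supported == 147
        assert round(100 * res.supported_fraction) == 82

    def test_array_false_negative_fractions(self):
        detected = {f"D{i}" for i in range(161)}
        proteome_only = {f"P{i}" for i in range(192)}
        probed = detected | proteome_only
        array = {f"P{i}" for i in range(8)} | {f"D{i}" for i in range(125)}
        res = detection_concordance(detected, proteome_only | detected, set(),
                                    array_detected=array, probed=probed)
        assert round(100 * res.proteome_only_array_fraction) == 4
        assert round(100 * res.detected_array_fraction) == 78

    def test_full_support_gives_one(self):
        detected = {"a", "b"}
        assert detection_concordance(detected, {"a", "b", "c"}, set()).supported_fraction == 1.0

    def test_empty_detected_errors(self):
        with pytest.raises(SchemaError):
            detection_concordance(set(), {"a"}, set())
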