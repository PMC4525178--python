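# lrnet

Ligand–receptor pair assembly and cell-to-cell communication network
inference from cell-type expression atlases.

Multicellular physiology runs on secreted ligands binding cell-surface
receptors. Given (i) a genes × cell-types TPM expression matrix, (ii)
curated ligand–receptor pair collections, (iii) protein–protein interaction
(PPI) tables, (iv) subcellular-localization evidence, and (v) protein age
and length tables, `lrnet` builds a directed, weighted, multi-edge network
in which cell types are nodes and every expressed ligand–receptor pair is a
potential communication path. It is written for computational biologists
who want the network construction, the enrichment statistics and the
evolutionary tests as tested, reusable library code rather than one-off
scripts.

## What it computes

- **Localization consensus** — tiered classification of proteins into
  {cytoplasm, multiple, nucleus, other, plasma_membrane, secreted, n/a}:
  curated annotation first (with a transmembrane-helix requirement for
  membrane claims), computational prediction as fallback.
- **Pair assembly** — provenance-tracked merge of curated pair sources,
  candidate expansion from secreted/plasma-membrane proteins, novel-pair
  inference from PPI evidence (binary experimental evidence, or
  STRING-style channels at confidence ≥ 700), and curation verdicts.
  Pairs with a primary-literature PMID are *reference*, the rest
  *putative*; excluded pairs never reach the network.
- **Thresholded networks** — a gene is detected at TPM ≥ t (t = 10 default;
  50, 100 presets). Per-cell ligand/receptor repertoires, autocrine
  fractions, specific/broad median-split quadrants, cell × cell path-count
  matrices, and explicit edge lists with weight = ligand TPM × receptor
  TPM, exportable as TSV, GraphML or JSON.
- **Lineage statistics** — per pair, the *major transmitter* (argmax ligand
  TPM) and *major receiver* (argmax receptor TPM); 6 × 6 lineage matrices;
  exact binomial tests for lineage over/under-representation
  (x ~ Binom(n, p₀) with p₀ = lineage share of cell types) and for
  path bias (p₀ = product of transmitter/receiver marginals), each family
  Benjamini–Hochberg adjusted.
- **Evolutionary tests** — phylostratum tallies of pairs; an empirical
  length-bias null p₀ = P(younger partner is shorter | length-discordant
  interacting pair); a one-sided exact binomial receptor-before-ligand test
  with a Clopper–Pearson one-sided 95% lower bound; Mann–Whitney
  comparisons of specificity and age across localization classes.
- **Synthetic data** — a deterministic generator for every input table,
  with planted lineage structure, planted novel pairs, and tunable
  receptor-older and younger-is-shorter probabilities, so the whole
  pipeline is testable end to end without downloads.

## Worked example

Generate a synthetic study and run the full pipeline:

```sh
lrnet simulate --seed 3 --out simdir
lrnet run-all --inputs simdir --out rundir
```

The run report (also written to `rundir/report.json`) prints per-stage
counts:

```json
{
 "stages": {
  "localization": {"n_records": 96},
  "pairs": {"n_known": 72, "n_inferred": 48, "n_active": 120, "n_excluded": 0},
  "network": {"n_expressed_pairs": 120, "n_edges": 10265},
  "lineage": {"n_major_pairs": 120},
  "evolution": {"x": 78, "n": 104, "p0": 0.567, "p": 8.5e-05, "ci_lower": 0.670}
 }
}
```

Reading the evolution stage: of 104 pairs whose partners originated at
different phylostrata, the ligand was the younger partner in 78. Against
the length-bias null of 0.567 (estimated from the simulated
length-discordant PPI control set), the one-sided binomial test gives
p ≈ 8.5 × 10⁻⁵ with a 95% lower confidence bound of 0.670 on the
ligand-younger proportion — the planted receptor-before-ligand excess is
recovered. Re-running with the same inputs reproduces the report
byte-for-byte.

The library surface mirrors the CLI; for instance the classic
high-expressor benchmark:

```python
>>> from lrnet import ExpressionAtlas, build_edges
>>> from lrnet.pairs import PairRecord, PairSet
>>> import pandas as pd
>>> atlas = ExpressionAtlas(pd.DataFrame(
...     {"mast cell, stimulated": [1109.0, 15.0],
...      "CD14+ endothelial progenitor": [12.0, 699.0]},
...     index=["CSF1", "CSF1R"]))
>>> top = build_edges(atlas, PairSet([PairRecord("CSF1", "CSF1R")]),
...                   threshold=10, top_n=1)[0]
>>> top.source_cell, top.target_cell, top.weight
('mast cell, stimulated', 'CD14+ endothelial progenitor', 775191.0)
```

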