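"""Synthetic pipeline inputs with the statistical structure the analysis assumes.

The generators emulate, at desk scale, the features the pipeline exploits in
a real cell-type expression atlas: heavy-tailed (log-normal) TPM values,
housekeeping genes expressed everywhere versus lineage-restricted genes
elevated in a home lineage and mostly absent (dropout) elsewhere, curated
pair sources with overlap, PPI evidence that lets pair inference recover
planted novel pairs, and phylostratum/length tables with a tunable
receptor-before-ligand excess and a tunable younger-is-shorter probability
for the length-bias control set.  Everything is a pure function of the
config: the same seed gives bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .localization import LocalizationEvidence
from .model import LINEAGES, ExpressionAtlas, SchemaError
from .pairs import KnownPairSource, PPIRecord


def _default_cells_per_lineage() -> Dict[str, int]:
    return {lineage: 4 for lineage in LINEAGES}


@dataclass
class SimulationConfig:
    """All generator knobs.

    Defaults are a deliberate scale-down of the real study: 24 cell types
    (4 per lineage) instead of 144, 300 genes, 120 planted pairs — enough
    structure for every stage to produce non-trivial output in seconds.
    TPM values are log-normal (natural-log mean ``tpm_mu`` = 2.2 gives a
    median of ~9 TPM, so roughly half of gene/cell values clear the 10 TPM
    detection threshold).  ``receptor_older_excess`` is the boost over the
    0.5 baseline of P(ligand younger | ages differ); ``younger_shorter_prob``
    is the planted probability that the shorter partner of a
    length-discordant control PPI is the younger one.
    """

    seed: int = 0
    n_cells_per_lineage: Dict[str, int] = field(default_factory=_default_cells_per_lineage)
    n_housekeeping: int = 180
    n_restricted: int = 120
    n_pairs: int = 120
    reference_fraction: float = 0.6  # fraction of planted pairs in the known sources
    tpm_mu: float = 2.2  # natural-log scale
    tpm_sigma: float = 1.0
    dropout_rate: float = 0.7  # restricted genes outside home lineage
    lineage_block_effect: float = 10.0  # fold-change in home lineage
    receptor_older_excess: float = 0.25  # epsilon; P(ligand younger | not tied) = 0.5 + eps
    younger_shorter_prob: float = 0.591  # planted q for the length-control PPI set
    tie_prob: float = 0.18  # P(same phylostratum) for planted pairs
    n_strata: int = 12
    n_length_ppi: int = 500  # length-discordant control PPIs
    n_decoy_ppi: int = 200
    n_sources: int = 3
    string_fraction: float = 0.5  # supported novel pairs via STRING-style vs HPRD-style rows
    biased_lineage: Optional[str] = None  # plant pair genes restricted to this lineage
    bias_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in ("reference_fraction", "dropout_rate", "younger_shorter_prob",
                     "tie_prob", "string_fraction", "bias_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SchemaError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= 0.5 + self.receptor_older_excess <= 1.0:
            raise SchemaError(
                f"receptor_older_excess={self.receptor_older_excess} puts "
                "P(ligand younger) outside [0, 1]"
            )
        if any(v < 0 for v in self.n_cells_per_lineage.values()):
            raise SchemaError("cell counts must be >= 0")


def _rng(cfg: SimulationConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), salt]))


def simulate_atlas(cfg: SimulationConfig) -> Tuple[ExpressionAtlas, dict, dict]:
    """Generate the TPM atlas, its lineage map and per-gene truth labels.

    Returns ``(atlas, lineage_map, truth)`` where ``truth`` maps each gene to
    its restricted home lineage, or None for housekeeping genes.
    """
    rng = _rng(cfg, 1)
    cells, lineage_map = [], {}
    for lineage in LINEAGES:
        for i in range(cfg.n_cells_per_lineage.get(lineage, 0)):
            name = f"{lineage}_{i}"
            cells.append(name)
            lineage_map[name] = lineage
    if not cells:
        raise SchemaError("simulate_atlas: zero cells configured")

    hk_genes = [f"HK{i:04d}" for i in range(cfg.n_housekeeping)]
    rs_genes = [f"RS{i:04d}" for i in range(cfg.n_restricted)]
    active_lineages = [l for l in LINEAGES if cfg.n_cells_per_lineage.get(l, 0) > 0]
    home = rng.choice(active_lineages, size=cfg.n_restricted)
    if cfg.biased_lineage is not None:
        # the planted lineage signal needs enough genes restricted to that
        # lineage for the pair generator to draw both roles from it
        n_needed = min(cfg.n_restricted, 2 * int(round(cfg.bias_fraction * cfg.n_pairs)))
        home[:n_needed] = cfg.biased_lineage
    truth: dict = {g: None for g in hk_genes}
    truth.update({g: str(h) for g, h in zip(rs_genes, home)})

    n_cells = len(cells)
    tpm = np.empty((cfg.n_housekeeping + cfg.n_restricted, n_cells))
    tpm[: cfg.n_housekeeping] = rng.lognormal(cfg.tpm_mu, cfg.tpm_sigma,
                                              size=(cfg.n_housekeeping, n_cells))
    base = rng.lognormal(cfg.tpm_mu, cfg.tpm_sigma, size=(cfg.n_restricted, n_cells))
    in_home = np.array([[lineage_map[c] == truth[g] for c in cells] for g in rs_genes])
    dropped = rng.random((cfg.n_restricted, n_cells)) < cfg.dropout_rate
    restricted = np.where(in_home, base * cfg.lineage_block_effect, np.where(dropped, 0.0, base))
    tpm[cfg.n_housekeeping:] = restricted

    atlas = ExpressionAtlas(tpm=pd.DataFrame(tpm, index=hk_genes + rs_genes, columns=cells))
    return atlas, lineage_map, truth


@dataclass
class PairsTruth:
    """Ground truth of the planted pair structure."""

    all_pairs: List[Tuple[str, str]]
    known_pairs: List[Tuple[str, str]]
    novel_pairs: List[Tuple[str, str]]  # planted with qualifying PPI support
    loc_evidence: List[LocalizationEvidence]


def simulate_pairs_and_ppi(
    cfg: SimulationConfig, genes: List[str], truth: Optional[dict] = None
) -> Tuple[List[KnownPairSource], List[PPIRecord], PairsTruth]:
    """Plant ligand-receptor pairs, split them into known sources plus
    PPI-supported novel pairs, and add decoy PPIs among non-candidate genes.

    Each planted pair uses one ligand gene and one receptor gene (roles are
    disjoint gene sets).  Known pairs land in 1-2 of the mock sources
    (overlap exercises provenance merging).  Every novel pair gets a
    qualifying PPI row — HPRD-style binary evidence or a STRING-style
    channel with confidence drawn in [700, 950] — so inference can recover
    exactly the planted set.  Decoy PPIs connect decoy genes (never in any
    candidate set) with STRING scores straddling the 700 boundary.
    When ``biased_lineage`` is set (and gene truth labels are given), a
    ``bias_fraction`` share of pairs draws both partners from genes
    restricted to that lineage.
    """
    if len(genes) < 2:
        raise SchemaError("simulate_pairs_and_ppi needs >= 2 genes")
    rng = _rng(cfg, 2)
    need = 2 * cfg.n_pairs
    if len(genes) < need:
        raise SchemaError(f"need {need} genes for {cfg.n_pairs} disjoint-role pairs")

    pool = list(genes)
    if cfg.biased_lineage is not None and truth:
        biased = [g for g in pool if truth.get(g) == cfg.biased_lineage]
        rest = [g for g in pool if truth.get(g) != cfg.biased_lineage]
        n_biased_pairs = min(int(round(cfg.bias_fraction * cfg.n_pairs)), len(biased) // 2)
        chosen_biased = list(rng.choice(biased, size=2 * n_biased_pairs, replace=False))
        n_rest = need - 2 * n_biased_pairs
        chosen_rest = list(rng.choice(rest, size=n_rest, replace=False))
        # interleave so bias spreads over both roles
        chosen = chosen_biased + chosen_rest
    else:
        chosen = list(rng.choice(pool, size=need, replace=False))
    ligands, receptors = chosen[::2], chosen[1::2]
    all_pairs = list(zip(ligands, receptors))

    n_known = int(round(cfg.reference_fraction * cfg.n_pairs))
    known_pairs, novel_pairs = all_pairs[:n_known], all_pairs[n_known:]

    source_pairs: List[List[Tuple[str, str]]] = [[] for _ in range(cfg.n_sources)]
    source_pmids: List[dict] = [{} for _ in range(cfg.n_sources)]
    for k, pair in enumerate(known_pairs):
        n_src = 1 + int(rng.random() < 0.4)  # ~40% of known pairs appear in two sources
        for s in rng.choice(cfg.n_sources, size=n_src, replace=False):
            source_pairs[s].append(pair)
            source_pmids[s][pair] = {f"PMID{k:05d}"}
    sources = [
        KnownPairSource(source_name=f"source_{s}", pairs=source_pairs[s], pmids=source_pmids[s])
        for s in range(cfg.n_sources)
    ]

    ppi: List[PPIRecord] = []
    hprd_types = ("in_vitro", "in_vivo", "yeast2hybrid")
    string_types = ("physical_binding", "experimental")
    for lig, rec in novel_pairs:
        a, b = (lig, rec) if rng.random() < 0.5 else (rec, lig)  # endpoint order is noise
        if rng.random() < cfg.string_fraction:
            ppi.append(PPIRecord(a, b, "string_like", str(rng.choice(string_types)),
                                 confidence=int(rng.integers(700, 951))))
        else:
            ppi.append(PPIRecord(a, b, "hprd_like", str(rng.choice(hprd_types))))
    decoys = [f"DEC{i:04d}" for i in range(2 * cfg.n_decoy_ppi)]
    for i in range(cfg.n_decoy_ppi):
        ppi.append(PPIRecord(decoys[2 * i], decoys[2 * i + 1], "string_like",
                             str(rng.choice(string_types)),
                             confidence=int(rng.integers(650, 751))))

    # localization evidence: novel-pair ligands secreted, receptors PM with TMHs,
    # so candidate expansion places them in the putative sets
    loc_evidence = [
        LocalizationEvidence(symbol=lig, predicted_class="secreted", tmh_count=0)
        for lig, _ in novel_pairs
    ] + [
        LocalizationEvidence(symbol=rec, predicted_class="plasma membrane",
                             tmh_count=int(rng.integers(1, 8)))
        for _, rec in novel_pairs
    ]
    return sources, ppi, PairsTruth(all_pairs, known_pairs, novel_pairs, loc_evidence)


@dataclass
class AgeLengthTables:
    """Synthetic age/length tables plus the length-discordant control PPI set."""

    ages: Dict[str, int]  # phylostratum rank; larger = younger
    mya: Dict[str, float]
    lengths: Dict[str, float]
    control_ppi: List[PPIRecord]


def simulate_ages_lengths(
    cfg: SimulationConfig, pairs: List[Tuple[str, str]]
) -> AgeLengthTables:
    """Assign phylostrata and lengths planting the receptor-before-ligand excess.

    For each pair the receptor stratum is drawn first (uniform over the
    interior ranks so both directions stay reachable); the partners tie with
    probability ``tie_prob``; otherwise the ligand is younger (a strictly
    larger rank) with probability 0.5 + ``receptor_older_excess``.  Ligand
    lengths are log-normal with median 267 aa and receptor lengths with
    median 515 aa.  A separate control set of ``n_length_ppi`` PPIs joins a
    short protein (uniform 80-260 aa) to a long one (uniform 520-1400 aa)
    with distinct ages, the shorter being the younger with probability
    ``younger_shorter_prob``.
    """
    rng = _rng(cfg, 3)
    if cfg.n_strata < 4:
        raise SchemaError("n_strata must be >= 4")
    p_younger = 0.5 + cfg.receptor_older_excess
    ages: Dict[str, int] = {}
    lengths: Dict[str, float] = {}
    for lig, rec in pairs:
        r_stratum = int(rng.integers(2, cfg.n_strata))  # interior: 2..n_strata-1
        if rng.random() < cfg.tie_prob:
            l_stratum = r_stratum
        elif rng.random() < p_younger:
            l_stratum = int(rng.integers(r_stratum + 1, cfg.n_strata + 1))
        else:
            l_stratum = int(rng.integers(1, r_stratum))
        ages[lig], ages[rec] = l_stratum, r_stratum
        lengths[lig] = float(np.round(rng.lognormal(np.log(267), 0.5)))
        lengths[rec] = float(np.round(rng.lognormal(np.log(515), 0.5)))

    control_ppi: List[PPIRecord] = []
    for i in range(cfg.n_length_ppi):
        short, long_ = f"LPS{i:04d}", f"LPL{i:04d}"
        lengths[short] = float(rng.integers(80, 261))
        lengths[long_] = float(rng.integers(520, 1401))
        young, old = sorted(rng.choice(np.arange(1, cfg.n_strata + 1), size=2, replace=False))
        old_rank, young_rank = int(young), int(old)  # larger rank = younger
        if rng.random() < cfg.younger_shorter_prob:
            ages[short], ages[long_] = young_rank, old_rank
        else:
            ages[short], ages[long_] = old_rank, young_rank
        a, b = (short, long_) if rng.random() < 0.5 else (long_, short)
        control_ppi.append(PPIRecord(a, b, "hprd_like", "in_vitro"))

    mya = {g: float((cfg.n_strata - rank) * 100) for g, rank in ages.items()}
    return AgeLengthTables(ages=ages, mya=mya, lengths=lengths, control_ppi=control_ppi)


# ---------------------------------------------------------------------------
# full input-directory writer for the CLI

def write_simulation(cfg: SimulationConfig, outdir) -> dict:
    """Write every input TSV the pipeline consumes, plus truth.json.

    Returns a manifest of the files written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from .io import write_expression_atlas

    atlas, lineage_map, gene_truth = simulate_atlas(cfg)
    sources, ppi, ptruth = simulate_pairs_and_ppi(cfg, atlas.genes, gene_truth)
    tables = simulate_ages_lengths(cfg, ptruth.all_pairs)

    write_expression_atlas(atlas, outdir / "atlas.tsv")
    pd.DataFrame(sorted(lineage_map.items()), columns=["cell_type", "lineage"]).to_csv(
        outdir / "lineage_map.tsv", sep="\t", index=False
    )
    for src in sources:
        pd.DataFrame(
            [(l, r, ";".join(sorted(src.pmids.get((l, r), ())))) for l, r in src.pairs],
            columns=["ligand", "receptor", "pmid"],
        ).to_csv(outdir / f"known_{src.source_name}.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(p.protein_a, p.protein_b, p.source, p.evidence_type,
          "" if p.confidence is None else p.confidence) for p in ppi + tables.control_ppi],
        columns=["protein_a", "protein_b", "source", "evidence_type", "confidence"],
    ).to_csv(outdir / "ppi.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(ev.symbol, ev.uniprot_class or "", ev.hprd_class or "",
          "PMID0" if ev.hprd_has_pmid else "", ev.predicted_class or "", ev.tmh_count)
         for ev in ptruth.loc_evidence],
        columns=["symbol", "uniprot_class", "hprd_class", "hprd_pmid",
                 "predicted_class", "tmh_count"],
    ).to_csv(outdir / "localization_evidence.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(g, r, tables.mya[g], "synthetic") for g, r in sorted(tables.ages.items())],
        columns=["symbol", "phylostratum", "mya", "method"],
    ).to_csv(outdir / "ages.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(tables.lengths.items()), columns=["symbol", "length_aa"]
    ).to_csv(outdir / "lengths.tsv", sep="\t", index=False)
    # empty curation table with the documented schema
    pd.DataFrame(columns=["ligand", "receptor", "verdict", "pmid"]).to_csv(
        outdir / "curation.tsv", sep="\t", index=False
    )

    truth = {
        "config": dataclasses.asdict(cfg),
        "restricted_lineage": gene_truth,
        "pairs": {
            "all": ptruth.all_pairs,
            "known": ptruth.known_pairs,
            "novel": ptruth.novel_pairs,
        },
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1, default=str))
    files = sorted(p.name for p in outdir.iterdir())
    return {"outdir": str(outdir), "files": files}
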