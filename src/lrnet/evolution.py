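"""Evolutionary-age analyses of ligand-receptor pairs.

Protein ages are integer phylostratum ranks where a *larger* rank means a
more recent origin.  The central question is whether receptors tend to
predate their cognate ligands.  Because ligands are systematically shorter
than receptors, and age-estimation methods can misdate short proteins, the
null probability for the "ligand younger" binomial test is estimated
empirically: among interacting protein pairs with one short (lower length
quartile) and one long (upper quartile) partner, the observed fraction in
which the younger partner is the shorter one.  The test itself is a
one-sided exact binomial with a Clopper-Pearson one-sided 95% lower
confidence bound on the ligand-younger proportion.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta, binomtest, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .model import SchemaError
from .network import _active
from .pairs import PPIRecord

logger = logging.getLogger(__name__)


@dataclass
class AgePairTally:
    """Pair counts by (ligand phylostratum, receptor phylostratum).

    ``matrix`` rows are ligand strata, columns receptor strata.  The three
    scalar counts partition the pairs with both ages known.
    """

    matrix: pd.DataFrame
    n_same: int
    n_ligand_younger: int
    n_ligand_older: int
    n_dropped_missing_age: int = 0

    @classmethod
    def from_counts(cls, n_same: int, n_ligand_younger: int, n_ligand_older: int) -> "AgePairTally":
        """Build a tally directly from summary counts (no per-stratum matrix)."""
        return cls(
            matrix=pd.DataFrame(),
            n_same=n_same,
            n_ligand_younger=n_ligand_younger,
            n_ligand_older=n_ligand_older,
        )


@dataclass
class BiasTestResult:
    """One-sided binomial test of the ligand-younger proportion against p0."""

    x: int
    n: int
    null_p0: float
    one_sided_p: float
    ci_lower: float  # one-sided exact (Clopper-Pearson) 95% lower bound
    estimate: float


def age_pair_tally(pairs, ages: Mapping[str, int]) -> AgePairTally:
    """Tally pairs by partner phylostrata; larger rank = younger (more recent)."""
    active = _active(pairs)
    usable = [(r.ligand, r.receptor) for r in active if r.ligand in ages and r.receptor in ages]
    n_dropped = len(active) - len(usable)
    if n_dropped:
        logger.warning("age_pair_tally: %d pairs dropped for missing ages", n_dropped)
    strata = sorted({ages[g] for lr in usable for g in lr})
    matrix = pd.DataFrame(0, index=strata, columns=strata, dtype=int)
    n_same = n_younger = n_older = 0
    for lig, rec in usable:
        ls, rs = ages[lig], ages[rec]
        matrix.at[ls, rs] += 1
        if ls == rs:
            n_same += 1
        elif ls > rs:
            n_younger += 1
        else:
            n_older += 1
    return AgePairTally(
        matrix=matrix,
        n_same=n_same,
        n_ligand_younger=n_younger,
        n_ligand_older=n_older,
        n_dropped_missing_age=n_dropped,
    )


@dataclass
class LengthBiasNull:
    p0: float
    n_younger_shorter: int
    n_pairs: int


def length_bias_null(
    ppi: Sequence[PPIRecord],
    lengths: Mapping[str, float],
    ages: Mapping[str, int],
) -> LengthBiasNull:
    """Estimate P(younger partner is the shorter one) from length-discordant PPIs.

    Quartile cuts are computed over *all* proteins in the length table;
    boundary values belong to the quartile (<= lower cut, >= upper cut).
    Qualifying PPIs have one partner in the lower and one in the upper
    quartile, both with known ages, ages not tied.
    """
    all_lengths = np.asarray(list(lengths.values()), dtype=float)
    if all_lengths.size == 0:
        raise SchemaError("length table is empty")
    q1, q3 = np.quantile(all_lengths, [0.25, 0.75])
    x = n = 0
    for rec in ppi:
        a, b = rec.protein_a, rec.protein_b
        if a not in lengths or b not in lengths or a not in ages or b not in ages:
            continue
        la, lb = lengths[a], lengths[b]
        short_long = (la <= q1 and lb >= q3) or (lb <= q1 and la >= q3)
        if not short_long or ages[a] == ages[b]:
            continue
        n += 1
        younger = a if ages[a] > ages[b] else b
        shorter = a if la < lb else b
        if younger == shorter:
            x += 1
    if n == 0:
        raise SchemaError("no qualifying length-discordant PPI pairs with distinct ages")
    return LengthBiasNull(p0=x / n, n_younger_shorter=x, n_pairs=n)


def receptor_first_test(tally: AgePairTally, p0: float) -> BiasTestResult:
    """One-sided exact binomial test that ligands are younger more often than p0.

    Same-stratum pairs are excluded: x = ligand-younger pairs, n = ligand-
    younger + ligand-older.  The confidence bound is the exact one-sided 95%
    Clopper-Pearson lower bound on x/n.
    """
    x = tally.n_ligand_younger
    n = x + tally.n_ligand_older
    if n == 0:
        raise SchemaError("receptor_first_test: no age-discordant pairs")
    if not (0 < p0 < 1):
        raise SchemaError("null probability p0 must be in (0, 1)")
    pval = binomtest(x, n, p0, alternative="greater").pvalue
    ci_lower = 0.0 if x == 0 else float(beta.ppf(0.05, x, n - x + 1))
    return BiasTestResult(
        x=x, n=n, null_p0=p0, one_sided_p=float(pval), ci_lower=ci_lower, estimate=x / n
    )


DEFAULT_COMPARISON_CLASSES = ("cytoplasm", "nucleus", "other", "plasma_membrane", "secreted")


def class_comparison(
    values: Mapping[str, float],
    classes: Mapping[str, str],
    metric_name: str = "metric",
    include_classes: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney U tests of a per-gene metric across
    localization classes, BH-adjusted over all class pairs.

    Classes with fewer than 2 members are skipped with a warning.  Returns
    one row per class pair with U, the two medians and means, p and q.
    """
    wanted = tuple(include_classes) if include_classes else DEFAULT_COMPARISON_CLASSES
    groups: dict = {}
    for gene, val in values.items():
        cls = classes.get(gene)
        if cls in wanted:
            groups.setdefault(cls, []).append(float(val))
    for cls in list(groups):
        if len(groups[cls]) < 2:
            logger.warning("class_comparison: class %r has <2 members, skipped", cls)
            del groups[cls]
    if len(groups) < 2:
        raise SchemaError("class_comparison needs >=2 classes with >=2 members each")
    rows = []
    for a, b in itertools.combinations(sorted(groups), 2):
        res = mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        rows.append(
            (
                metric_name,
                a,
                b,
                len(groups[a]),
                len(groups[b]),
                float(res.statistic),
                float(np.median(groups[a])),
                float(np.median(groups[b])),
                float(np.mean(groups[a])),
                float(np.mean(groups[b])),
                float(res.pvalue),
            )
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "metric",
            "class_a",
            "class_b",
            "n_a",
            "n_b",
            "U",
            "median_a",
            "median_b",
            "mean_a",
            "mean_b",
            "p",
        ],
    )
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df


def specificity_score(det_row, method: str = "breadth") -> float:
    """Cell-type specificity of one gene from its boolean detection row.

    ``breadth`` (default): 1 - breadth/n_cells, i.e. 1 - epsilon for a gene
    detected in a single cell type down to 0 for a ubiquitous gene.
    ``entropy``: 1 - H(detection)/log(n_cells) over the detected-cell
    indicator, an alternative that also lives in [0, 1].
    """
    row = np.asarray(det_row, dtype=bool)
    if row.size == 0:
        raise SchemaError("specificity_score needs >= 1 cell")
    k = int(row.sum())
    n = row.size
    if method == "breadth":
        return 1.0 - k / n
    if method == "entropy":
        if k == 0 or n == 1:
            return 1.0
        p = np.full(k, 1.0 / k)
        h = float(-(p * np.log(p)).sum())
        return 1.0 - h / np.log(n)
    raise SchemaError(f"unknown specificity method {method!r}")


def read_age_table(path) -> dict:
    """Read symbol -> phylostratum rank from a TSV (symbol, phylostratum[, mya, method])."""
    from .io import read_table, normalize_symbol

    df = read_table(path, ["symbol", "phylostratum"])
    return {normalize_symbol(s): int(p) for s, p in zip(df["symbol"], df["phylostratum"])}


def read_length_table(path) -> dict:
    from .io import read_table, normalize_symbol

    df = read_table(path, ["symbol", "length_aa"])
    return {normalize_symbol(s): float(v) for s, v in zip(df["symbol"], df["length_aa"])}
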