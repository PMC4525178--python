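# Methods

This note documents the models, rules and statistical procedures `lrnet`
implements, the choices made where a procedure was genuinely open, and what
the synthetic-data generator does and does not emulate.

## Expression atlas and detection

The atlas is a genes × cell-types matrix of TPM values. When built from
per-sample libraries, a replicate map collapses samples to cell types by the
arithmetic mean of per-sample TPM; no re-normalization is applied after
averaging, and a cell type with a single library is its own mean. Gene
symbols are trimmed, uppercased and resolved through a user-supplied alias
table only — no live nomenclature queries, so results are reproducible from
the input files alone.

A gene is *detected* in a cell type when its TPM is at or above the working
threshold. The default is 10 TPM (roughly three transcript copies per cell
under CAGE calibration), with 50 and 100 TPM as the other standard presets.
The comparison operator is `>=` by default and exposed as an option: a value
exactly at the threshold counts as detected. All derived counts
(repertoires, expressed pairs, path counts, edges) are therefore
non-increasing in the threshold, a property the test suite checks.

Genes referenced by a pair table but absent from the atlas are treated as
never detected, with a logged warning rather than an error: real pair
collections always contain genes outside any one expression panel.

## Localization consensus

Proteins are classified into cytoplasm, multiple, nucleus, other,
plasma_membrane, secreted or n/a by two evidence tiers with strict
precedence. Tier 1 uses curated annotation: UniProt-style experimental or
probable localizations are accepted directly; HPRD-style annotations are
accepted when backed by a PubMed ID, except that a plasma-membrane
annotation additionally requires at least one predicted transmembrane helix
(TMH). Tier 2 applies only when Tier 1 yields nothing: a computational
prediction is accepted with TMH sanity constraints (plasma membrane needs
≥ 1 TMH; secreted tolerates at most 1), otherwise the protein is
unclassifiable (n/a).

Open points resolved here: when UniProt and HPRD disagree, UniProt wins and
HPRD contributes nothing (sources are consulted in precedence order, not
pooled). A single source reporting two or more distinct compartments yields
the class "multiple". Compartments outside the four core ones collapse to
"other" through a configurable mapping table. The secreted class carries no
TMH constraint at Tier 1 — the annotation-tier TMH requirement applies to
plasma-membrane claims only.

## Pair assembly

Known directed (ligand, receptor) pairs from several curated sources are
merged with full provenance; the same unordered pair appearing with swapped
roles across sources is a hard error, since roles are directional curation
decisions. Candidate ligands are the known ligands, orphan ligands and
secreted proteins not already known as receptors; candidate receptors
mirror this with plasma-membrane proteins.

A PPI supports a candidate pair when its endpoints match one candidate from
each set and the evidence qualifies: HPRD-style binary evidence of type
in vitro, in vivo or yeast two-hybrid, or a STRING-style physical-binding
or experimental channel with confidence ≥ 700 (the boundary is inclusive;
the two channels are evaluated independently). Endpoint order is ignored —
undirected evidence supports a directed pair. Self-pairs (the same symbol
in both roles) are excluded by default with an override flag.

Curation verdicts (keep / exclude / add, each optionally with a PMID) are
applied last. A pair with at least one PMID is *reference*, otherwise
*putative*; excluded pairs are retained with a reason but never reach the
network modules (enforced by the `PairSet.active()` surface and tested).

## Network statistics

For expressed pairs (ligand and receptor each detected somewhere, not
necessarily the same cell) the module computes per-cell
ligand/receptor repertoires, autocrine fractions (the share of a cell's
expressed ligands whose cognate receptor is also on that cell, and the
reciprocal), gene breadth (number of detecting cell types), and a median
split into specific vs broad per role. The tie rule is breadth ≤ median ⇒
specific, which keeps the median gene itself specific. Path-count matrices
cover all ordered cell pairs including the diagonal; the diagonal equals
the per-cell autocrine pair count by construction, and this identity is
tested. Edge weights are exactly ligand TPM × receptor TPM; top-N edge
filtering breaks weight ties lexicographically on (ligand, receptor,
source cell, target cell) for determinism. Autocrine self-edges are genuine
edges and included by default.

The detection–proteome concordance helper computes the supported fraction
|detected ∩ (proteome ∪ literature)| / |detected| and, when an array data
set with a probed-gene universe is supplied, the array-detected fraction
among proteome-only genes (candidate transcriptomic false negatives) and
among detected genes (positive control).

## Lineage statistics

For each expressed pair, the cell with the highest ligand TPM is the major
transmitter and the cell with the highest receptor TPM the major receiver;
argmax ties go to the lexicographically smallest cell-type name. Pairs
whose ligand or receptor never exceeds zero are excluded with a warning.

Two exact binomial test families follow, both two-sided with
Benjamini–Hochberg adjustment within the family (directionality is
reported separately):

- *Representation* (12 tests: 6 lineages × 2 roles): x = pairs whose
  maximal cell lies in the lineage, n = pairs, null p₀ = the lineage's
  share of cell types.
- *Path bias* (36 tests: ordered lineage pairs): x = the lineage-matrix
  cell, n = total pairs, null p₀ = product of the max-transmitter and
  max-receiver marginals, deliberately ignoring lineage sizes. A
  permutation variant (receivers permuted against transmitters) is
  available as an option.

Calibration, measured by simulation in the test suite and the acceptance
script: with pairs drawn uniformly over a 144-cell panel
(63/34/29/9/5/4 cells per lineage, 1,287 pairs, 1,000 replicates), the
representation family rejects true nulls at the nominal 5% rate
(pooled rate ≈ 0.048). The path-bias family is markedly conservative
(pooled rate ≈ 0.016): its null probability is estimated from the same
matrix's marginals, which shrinks apparent deviations, and the exact
binomial is additionally conservative at the small cell probabilities this
design produces (even with the true generating marginals supplied, the
pooled rate is ≈ 0.040). Conservatism means the test's significance calls
are trustworthy but its power is understated; users comparing many weak
path biases should prefer the permutation variant.

## Evolutionary-age analysis

Ages are integer phylostratum ranks; a larger rank means a more recent
origin (mya values, when given, are converted through the age table's
declared ordering). Pairs tally into ligand-younger / same-stratum /
ligand-older; pairs with a missing age are dropped with a reported count.

Because ligands (median ≈ 267 aa) are shorter than receptors
(median ≈ 515 aa) and age estimation can misdate short proteins, the null
for the directional test is estimated from data: among interacting protein
pairs with one partner in the lower length quartile and one in the upper
(quartiles over all proteins in the length table; boundary values belong to
the quartile), the fraction in which the younger partner is the shorter
one. Age ties are excluded from this denominator. The receptor-first test
is then a one-sided exact binomial of the ligand-younger proportion against
that null, with an exact one-sided 95% Clopper–Pearson lower bound on the
proportion. On the published counts (1,082 of 1,513 against 0.591) this
gives p ≈ 7×10⁻²⁴ and a lower bound of 0.695.

Class comparisons (specificity or age across localization classes) are
two-sided Mann–Whitney U tests over all class pairs with BH adjustment;
classes with fewer than two members are skipped. The default comparison
covers cytoplasm, nucleus, other, plasma_membrane and secreted; "multiple"
and "n/a" join only on request. The specificity score is 1 − breadth/n
(1 − ε for a gene in one cell type, 0 for ubiquitous); an entropy-based
variant is available. This score is a declared stand-in: it is monotone in
breadth and bounded in [0, 1], which is all the downstream comparisons use.

## Synthetic data

The generator produces every input the pipeline consumes as a pure
function of its config (same seed → bit-identical outputs). Defaults are a
deliberate scale-down of a real atlas study: 24 cell types (4 per lineage),
300 genes (180 housekeeping + 120 lineage-restricted), 120 planted pairs,
running in seconds.

TPM values are log-normal (ln-scale mean 2.2, σ 1.0; median ≈ 9 TPM, so
the 10 TPM threshold splits the distribution near its middle).
Lineage-restricted genes are multiplied by a 10× block effect in their
home lineage and zeroed with probability 0.7 (dropout) elsewhere —
the simplest generator producing heavy-tailed expression with
lineage-blocked structure. Planted pairs split into known pairs spread over
three overlapping mock sources (with PMIDs) and novel pairs, each given one
qualifying PPI row (HPRD-style, or STRING-style with confidence in
[700, 950]); decoy PPIs among genes outside every candidate set draw
scores straddling the 700 boundary. Ages plant
P(ligand younger | not tied) = 0.5 + ε (default ε = 0.25) with an 18%
same-stratum probability; lengths are log-normal around the 267/515 aa
medians. A separate control set of length-discordant PPIs (short partner
80–260 aa, long partner 520–1400 aa) plants the younger-is-shorter
probability q (default 0.591) for the null estimator; the generator
returns this control set alongside the age and length tables because the
three are only meaningful together.

What the generator does *not* emulate: promoter-level structure,
replicate-level library noise, correlated gene modules beyond the single
lineage block, compositional constraints of real TPM normalization, and
database-snapshot idiosyncrasies of real pair sources. Passing recovery
tests therefore show that the machinery is correct and calibrated under
the assumed structure, not that real-atlas headline numbers are
reproduced — those depend on the original data snapshots and are quoted in
the README only as context.

## Numerical and determinism notes

TSVs are written with 6 significant digits; round-tripping is exact at
that precision. All randomness flows through `numpy` Generators seeded
from explicit integers; pipeline re-runs with identical inputs and config
produce byte-identical reports (hash-checked in tests). Degenerate inputs
fail loudly: empty detected sets, zero-total lineage matrices, all-tied
age tables, unmapped cell types and malformed schemas raise a schema error
(CLI exit code 2) naming the offending stage or rows.

## Problem sizes used in the checks

Oracle-equivalence checks run on random instances of ≤ 20 genes × 6 cells,
where brute-force enumeration is exact and instant. Calibration uses 1,000
replicates of 1,287 pairs on the 144-cell panel; recovery uses 100 seeded
pipeline runs at the default scale-down plus a 1,500-pair age table. The
full test suite and the acceptance script each complete in a few minutes
on one CPU.
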