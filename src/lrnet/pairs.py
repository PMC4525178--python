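"""Assembly of the non-redundant ligand-receptor pair set.

Known pairs from several curated sources are merged with full provenance;
candidate ligand/receptor sets are expanded with secreted and
plasma-membrane proteins; novel pairs are inferred from protein-protein
interaction (PPI) evidence (HPRD-style binary evidence, or STRING-style
channels at a confidence cutoff); and a manual curation table applies the
final keep/exclude/add verdicts.  A pair with at least one primary-literature
PMID is "reference", otherwise "putative"; excluded pairs are retained with
a reason but never reach the network modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .localization import LocalizationRecord
from .model import SchemaError

logger = logging.getLogger(__name__)

HPRD_EVIDENCE = {"in_vitro", "in_vivo", "yeast2hybrid"}
STRING_EVIDENCE = {"physical_binding", "experimental"}
DEFAULT_MIN_STRING_SCORE = 700


@dataclass
class KnownPairSource:
    """One curated database of directed (ligand, receptor) pairs."""

    source_name: str
    pairs: List[Tuple[str, str]]
    pmids: dict = field(default_factory=dict)  # (ligand, receptor) -> set of PMIDs

    def __post_init__(self) -> None:
        seen = set()
        for lr in self.pairs:
            if lr in seen:
                raise SchemaError(f"{self.source_name}: duplicate pair {lr}")
            seen.add(lr)


@dataclass(frozen=True)
class PPIRecord:
    """An undirected PPI with its evidence channel.

    ``confidence`` is required for string_like records (the combined-score
    convention, 0-1000) and absent for hprd_like binary evidence.
    """

    protein_a: str
    protein_b: str
    source: str  # hprd_like | string_like
    evidence_type: str
    confidence: Optional[int] = None

    def __post_init__(self) -> None:
        if self.source not in ("hprd_like", "string_like"):
            raise SchemaError(f"unknown PPI source {self.source!r}")
        if (self.confidence is not None) != (self.source == "string_like"):
            raise SchemaError(
                f"PPI {self.protein_a}-{self.protein_b}: confidence must be present "
                "iff source is string_like"
            )


@dataclass
class PairRecord:
    ligand: str
    receptor: str
    status: str = "putative"  # reference | putative | excluded
    sources: Set[str] = field(default_factory=set)
    pmids: Set[str] = field(default_factory=set)
    inferred: bool = False
    reason: str = ""

    @property
    def key(self) -> Tuple[str, str]:
        return (self.ligand, self.receptor)


class PairSet:
    """A keyed collection of PairRecords, unique on (ligand, receptor)."""

    def __init__(self, records: Iterable[PairRecord] = ()) -> None:
        self._records: dict = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: PairRecord) -> None:
        """Insert or merge a record (union of sources and PMIDs)."""
        existing = self._records.get(rec.key)
        if existing is None:
            self._records[rec.key] = rec
        else:
            existing.sources |= rec.sources
            existing.pmids |= rec.pmids
            existing.inferred = existing.inferred and rec.inferred

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, key) -> bool:
        return tuple(key) in self._records

    def __getitem__(self, key) -> PairRecord:
        return self._records[tuple(key)]

    def __iter__(self):
        return iter(self._records.values())

    def active(self) -> List[PairRecord]:
        """Non-excluded pairs — the only ones network modules may see."""
        return [r for r in self._records.values() if r.status != "excluded"]

    @property
    def ligands(self) -> Set[str]:
        return {r.ligand for r in self.active()}

    @property
    def receptors(self) -> Set[str]:
        return {r.receptor for r in self.active()}


def merge_known(sources: Sequence[KnownPairSource]) -> PairSet:
    """Union of directed pairs across sources with provenance.

    Roles are directional: the same unordered gene pair appearing with
    swapped ligand/receptor roles in different sources is a curation
    conflict and raises an error listing the offenders.
    """
    if not sources:
        raise SchemaError("merge_known requires at least one source")
    ps = PairSet()
    for src in sources:
        for (lig, rec) in src.pairs:
            ps.add(
                PairRecord(
                    ligand=lig,
                    receptor=rec,
                    sources={src.source_name},
                    pmids=set(src.pmids.get((lig, rec), ())),
                )
            )
    conflicts = sorted(
        {tuple(sorted(k)) for k in (r.key for r in ps) if k[::-1] in ps and k[0] != k[1]}
    )
    if conflicts:
        raise SchemaError(f"pairs appear with swapped ligand/receptor roles: {conflicts}")
    return ps


def build_candidates(
    known: PairSet,
    orphan_ligands: Set[str],
    orphan_receptors: Set[str],
    loc: Sequence[LocalizationRecord],
) -> Tuple[Set[str], Set[str]]:
    """Expand candidate ligand/receptor sets from localization classes.

    Putative ligands are the known ligands, orphan ligands, and secreted
    proteins not already known as receptors; putative receptors are the
    known receptors, orphan receptors, and plasma-membrane proteins not
    already known as ligands.
    """
    known_ligands = known.ligands
    known_receptors = known.receptors
    secreted = {r.symbol for r in loc if r.cls == "secreted"}
    pm = {r.symbol for r in loc if r.cls == "plasma_membrane"}
    putative_ligands = known_ligands | set(orphan_ligands) | (secreted - known_receptors)
    putative_receptors = known_receptors | set(orphan_receptors) | (pm - known_ligands)
    return putative_ligands, putative_receptors


def _ppi_supports(rec: PPIRecord, min_string_score: int) -> bool:
    if rec.source == "hprd_like":
        return rec.evidence_type in HPRD_EVIDENCE
    return rec.evidence_type in STRING_EVIDENCE and rec.confidence >= min_string_score


def infer_from_ppi(
    candidates: Tuple[Set[str], Set[str]],
    ppi: Sequence[PPIRecord],
    min_string_score: int = DEFAULT_MIN_STRING_SCORE,
    allow_self_pairs: bool = False,
) -> List[PairRecord]:
    """Infer directed (ligand, receptor) pairs from undirected PPI evidence.

    Endpoint order in the PPI is ignored: either orientation with the ligand
    endpoint in the candidate-ligand set and the receptor endpoint in the
    candidate-receptor set yields a pair.  Self-pairs (same symbol in both
    roles) are excluded unless ``allow_self_pairs``.  The STRING channels
    (physical binding, experimental) are evaluated independently at the
    inclusive ``>= min_string_score`` cutoff.
    """
    if min_string_score < 0:
        raise SchemaError("min_string_score must be >= 0")
    ligs, recs = candidates
    inferred: dict = {}
    for rec in ppi:
        if not _ppi_supports(rec, min_string_score):
            continue
        for lig, rcp in ((rec.protein_a, rec.protein_b), (rec.protein_b, rec.protein_a)):
            if lig == rcp and not allow_self_pairs:
                continue
            if lig in ligs and rcp in recs:
                key = (lig, rcp)
                if key not in inferred:
                    inferred[key] = PairRecord(
                        ligand=lig, receptor=rcp, inferred=True, sources=set()
                    )
                inferred[key].sources.add(f"{rec.source}:{rec.evidence_type}")
    return [inferred[k] for k in sorted(inferred)]


VALID_VERDICTS = {"keep", "exclude", "add"}


def apply_curation(
    merged: PairSet,
    inferred: Sequence[PairRecord],
    curation: Sequence[Tuple[str, str, str, Optional[str]]],
) -> PairSet:
    """Apply manual curation verdicts to the union of known and inferred pairs.

    ``curation`` rows are (ligand, receptor, verdict, pmid) with verdict one
    of keep/exclude/add.  The final status is "reference" iff the pair has at
    least one PMID, else "putative"; excluded pairs are retained with reason
    "curation_exclude" but filtered from .active().
    """
    final = PairSet()
    for rec in merged:
        final.add(
            PairRecord(
                ligand=rec.ligand,
                receptor=rec.receptor,
                sources=set(rec.sources),
                pmids=set(rec.pmids),
                inferred=rec.inferred,
            )
        )
    for rec in inferred:
        final.add(
            PairRecord(
                ligand=rec.ligand,
                receptor=rec.receptor,
                sources=set(rec.sources),
                pmids=set(rec.pmids),
                inferred=True,
            )
        )
    for row in curation:
        lig, rcp, verdict = row[0], row[1], row[2]
        pmid = row[3] if len(row) > 3 else None
        if verdict not in VALID_VERDICTS:
            raise SchemaError(f"unknown curation verdict {verdict!r} for ({lig}, {rcp})")
        key = (lig, rcp)
        if verdict == "add":
            final.add(PairRecord(ligand=lig, receptor=rcp, sources={"curation"}))
        if verdict in ("keep", "add") and pmid:
            if key in final:
                final[key].pmids.add(str(pmid))
        if verdict == "exclude":
            if key in final:
                final[key].status = "excluded"
                final[key].reason = "curation_exclude"
            else:
                logger.warning("curation excludes unknown pair %s", key)
    for rec in final:
        if rec.status != "excluded":
            rec.status = "reference" if rec.pmids else "putative"
    return final


# ---------------------------------------------------------------------------
# TSV interfaces (shape of the published supplementary pair table)

def read_known_pair_source(path, source_name: Optional[str] = None) -> KnownPairSource:
    from .io import read_table, normalize_symbol

    df = read_table(path, ["ligand", "receptor"])
    name = source_name or str(path)
    pairs, pmids = [], {}
    for _, row in df.iterrows():
        key = (normalize_symbol(row["ligand"]), normalize_symbol(row["receptor"]))
        if key not in pmids:
            pairs.append(key)
            pmids[key] = set()
        if "pmid" in df.columns and pd.notna(row.get("pmid")) and str(row["pmid"]).strip():
            pmids[key].add(str(row["pmid"]).strip())
    return KnownPairSource(source_name=name, pairs=pairs, pmids=pmids)


def read_ppi_table(path) -> List[PPIRecord]:
    from .io import read_table, normalize_symbol

    df = read_table(path, ["protein_a", "protein_b", "source", "evidence_type"])
    out = []
    for _, row in df.iterrows():
        conf = row.get("confidence")
        out.append(
            PPIRecord(
                protein_a=normalize_symbol(row["protein_a"]),
                protein_b=normalize_symbol(row["protein_b"]),
                source=row["source"],
                evidence_type=row["evidence_type"],
                confidence=None if pd.isna(conf) else int(conf),
            )
        )
    return out


def read_curation_table(path) -> List[Tuple[str, str, str, Optional[str]]]:
    from .io import read_table, normalize_symbol

    df = read_table(path, ["ligand", "receptor", "verdict"])
    rows = []
    for _, row in df.iterrows():
        pmid = row.get("pmid")
        rows.append(
            (
                normalize_symbol(row["ligand"]),
                normalize_symbol(row["receptor"]),
                str(row["verdict"]),
                None if pmid is None or pd.isna(pmid) else str(pmid),
            )
        )
    return rows


def write_pair_set(ps: PairSet, path) -> None:
    rows = [
        (
            r.ligand,
            r.receptor,
            r.status,
            ";".join(sorted(r.sources)),
            ";".join(sorted(r.pmids)),
            int(r.inferred),
        )
        for r in sorted(ps, key=lambda r: r.key)
    ]
    pd.DataFrame(
        rows, columns=["ligand", "receptor", "status", "sources", "pmids", "inferred"]
    ).to_csv(path, sep="\t", index=False)


def read_pair_set(path) -> PairSet:
    from .io import read_table

    df = read_table(path, ["ligand", "receptor", "status"])
    ps = PairSet()
    for _, row in df.iterrows():
        sources = str(row.get("sources", "") or "")
        pmids = str(row.get("pmids", "") or "")
        rec = PairRecord(
            ligand=row["ligand"],
            receptor=row["receptor"],
            status=row["status"],
            sources={s for s in sources.split(";") if s and s != "nan"},
            pmids={p for p in pmids.split(";") if p and p != "nan"},
            inferred=bool(int(row.get("inferred", 0) or 0)),
        )
        ps.add(rec)
        ps[rec.key].status = rec.status
    return ps
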