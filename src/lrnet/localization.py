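"""Tiered consensus classification of protein subcellular localization.

Proteins are assigned to one of seven classes — cytoplasm, multiple,
nucleus, other, plasma_membrane, secreted, n/a — from three evidence
sources in strict precedence order:

Tier 1 (annotation): curated UniProt-style localizations (experimental or
probable) are accepted directly; HPRD-style annotations are accepted when
they carry a PubMed ID, except that a plasma-membrane annotation
additionally requires at least one predicted transmembrane helix (TMH).
UniProt outranks HPRD; a lower-precedence source never contributes once a
higher one yields an accepted class.

Tier 2 (prediction): computational predictions are used only when no Tier-1
class was accepted, with TMH sanity constraints — plasma membrane needs
>= 1 TMH and secreted at most 1 TMH; predictions failing these are
unclassifiable ("n/a").

A source reporting two or more distinct accepted compartments yields the
class "multiple".  Compartments outside the four core ones map to "other".
"""

from __future__ import annotations

import collections
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

from .model import SchemaError

LOCALIZATION_CLASSES = (
    "cytoplasm",
    "multiple",
    "nucleus",
    "other",
    "plasma_membrane",
    "secreted",
    "n/a",
)

#: core compartments; everything else collapses to "other"
_CORE = {"cytoplasm", "nucleus", "plasma_membrane", "secreted"}

#: default mapping of raw compartment spellings to canonical labels;
#: extend via the ``compartment_map`` argument (shipped as config in the CLI)
DEFAULT_COMPARTMENT_MAP = {
    "cytoplasm": "cytoplasm",
    "cytosol": "cytoplasm",
    "cytoplasmic": "cytoplasm",
    "nucleus": "nucleus",
    "nuclear": "nucleus",
    "plasma membrane": "plasma_membrane",
    "plasma_membrane": "plasma_membrane",
    "pm": "plasma_membrane",
    "cell membrane": "plasma_membrane",
    "secreted": "secreted",
    "extracellular": "secreted",
    "multiple": "multiple",
}


@dataclass
class LocalizationEvidence:
    """Raw evidence for one protein.

    Class fields may carry several ';'-separated compartments.  ``tmh_count``
    is the number of predicted transmembrane helices.
    """

    symbol: str
    uniprot_class: Optional[str] = None
    hprd_class: Optional[str] = None
    hprd_has_pmid: bool = False
    predicted_class: Optional[str] = None
    tmh_count: int = 0

    def __post_init__(self) -> None:
        if self.tmh_count < 0:
            raise SchemaError(f"{self.symbol}: tmh_count must be >= 0")


@dataclass(frozen=True)
class LocalizationRecord:
    symbol: str
    cls: str
    tier: Optional[int]  # 1, 2, or None for n/a
    rationale: str


def map_compartment(raw: str, compartment_map: Optional[Mapping[str, str]] = None) -> str:
    key = str(raw).strip().lower()
    table = DEFAULT_COMPARTMENT_MAP if compartment_map is None else {
        **DEFAULT_COMPARTMENT_MAP,
        **{k.lower(): v for k, v in compartment_map.items()},
    }
    mapped = table.get(key, key)
    return mapped if mapped in _CORE or mapped == "multiple" else "other"


def _parse_classes(field: Optional[str], compartment_map) -> list:
    if field is None or not str(field).strip() or pd.isna(field):
        return []
    return [map_compartment(part, compartment_map) for part in str(field).split(";") if part.strip()]


def _consensus(classes: list) -> str:
    distinct = sorted(set(classes))
    if not distinct:
        return ""
    if "multiple" in distinct or len(distinct) > 1:
        return "multiple"
    return distinct[0]


def classify_localization(
    ev: LocalizationEvidence,
    compartment_map: Optional[Mapping[str, str]] = None,
) -> LocalizationRecord:
    """Classify one protein; total and deterministic on valid evidence."""
    # Tier 1a: UniProt experimental/probable annotations, accepted directly
    uni = _parse_classes(ev.uniprot_class, compartment_map)
    if uni:
        return LocalizationRecord(ev.symbol, _consensus(uni), 1, "uniprot")

    # Tier 1b: HPRD with PMID; PM additionally requires >= 1 predicted TMH
    if ev.hprd_has_pmid:
        hprd = _parse_classes(ev.hprd_class, compartment_map)
        accepted = [c for c in hprd if not (c == "plasma_membrane" and ev.tmh_count < 1)]
        if accepted:
            rationale = "hprd" if len(accepted) == len(hprd) else "hprd_pm_rejected_no_tmh"
            return LocalizationRecord(ev.symbol, _consensus(accepted), 1, rationale)

    # Tier 2: prediction, with TMH constraints on PM and secreted
    pred = _parse_classes(ev.predicted_class, compartment_map)
    if pred:
        cls = _consensus(pred)
        if cls == "plasma_membrane" and ev.tmh_count < 1:
            return LocalizationRecord(ev.symbol, "n/a", None, "predicted_pm_no_tmh")
        if cls == "secreted" and ev.tmh_count > 1:
            return LocalizationRecord(ev.symbol, "n/a", None, "predicted_secreted_tmh_gt1")
        return LocalizationRecord(ev.symbol, cls, 2, "predicted")

    return LocalizationRecord(ev.symbol, "n/a", None, "no_evidence")


def classify_all(
    evidence: Iterable[LocalizationEvidence],
    compartment_map: Optional[Mapping[str, str]] = None,
) -> list:
    return [classify_localization(ev, compartment_map) for ev in evidence]


def class_counts(records: Iterable[LocalizationRecord]) -> dict:
    """Tally records per class over all seven labels; sums to the input length."""
    counts = collections.Counter(r.cls for r in records)
    return {cls: counts.get(cls, 0) for cls in LOCALIZATION_CLASSES}


def read_localization_evidence(path) -> list:
    """Read the evidence TSV: symbol, uniprot_class, hprd_class, hprd_pmid, predicted_class, tmh_count."""
    from .io import read_table, normalize_symbol

    df = read_table(path, ["symbol", "tmh_count"])

    def opt(row, col):
        v = row.get(col)
        return None if v is None or (isinstance(v, float) and pd.isna(v)) or v == "" else str(v)

    out = []
    for _, row in df.iterrows():
        pmid = row.get("hprd_pmid")
        out.append(
            LocalizationEvidence(
                symbol=normalize_symbol(row["symbol"]),
                uniprot_class=opt(row, "uniprot_class"),
                hprd_class=opt(row, "hprd_class"),
                hprd_has_pmid=bool(pmid) and not (isinstance(pmid, float) and pd.isna(pmid)),
                predicted_class=opt(row, "predicted_class"),
                tmh_count=int(row["tmh_count"]),
            )
        )
    return out


def write_localization_records(records: Iterable[LocalizationRecord], path) -> None:
    pd.DataFrame(
        [(r.symbol, r.cls, "" if r.tier is None else r.tier, r.rationale) for r in records],
        columns=["symbol", "class", "tier", "rationale"],
    ).to_csv(path, sep="\t", index=False)
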