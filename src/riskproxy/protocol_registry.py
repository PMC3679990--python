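"""Protocol knowledge base and the registry-based risk algorithm.

A pediatric cancer registry records treatment protocol names and age at
diagnosis but rarely the biologic prognosticators used for risk
stratification.  The registry-based algorithm therefore proxies disease
risk from two inputs only:

* the risk class (SR/HR) that treating physicians of the era would have
  assigned to the treatment protocol, looked up by normalized protocol name
  in an a-priori knowledge base; and
* age at diagnosis: children aged <1 or >=10 years are high risk regardless
  of protocol.

The built-in knowledge base ships the sixteen cooperative-group protocols
used during the study period.  Eligibility metadata (lineage, age and WBC
ranges, genetics) is stored verbatim as documentation but never evaluated:
classification uses only the name -> risk mapping and age.

When a registry lists several protocols for one child (toxicity, slow
response, new prognostic information), disambiguation keeps the first
protocol plus anything starting within four weeks (28 days, inclusive) of
it, prefers a specific named protocol over a generic descriptor such as
"three drug induction", and among specific protocols takes the one with the
later start date, which better reflects prognosticators that emerge shortly
after diagnosis.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .cohort_model import ProtocolRecord, RiskCall, RiskLabel, RiskSource

__all__ = [
    "ProtocolEntry",
    "ProtocolTable",
    "normalize_protocol_name",
    "select_protocol",
    "protocol_risk",
    "classify_registry",
    "classify_cohort_registry",
    "load_protocol_table",
    "GENERIC_NAMES",
]

logger = logging.getLogger(__name__)

# Generic (non-specific) treatment descriptors seen in registry data.
GENERIC_NAMES = frozenset(
    {
        "THREE DRUG INDUCTION",
        "FOUR DRUG INDUCTION",
        "STANDARD INDUCTION",
        "INDUCTION",
        "CHEMOTHERAPY",
    }
)

_PUNCT_RE = re.compile(r"[-_./\\]")
_WS_RE = re.compile(r"\s+")

PROTOCOL_WINDOW_DAYS = 28  # "within four weeks", inclusive


@dataclass(frozen=True)
class ProtocolEntry:
    """One knowledge-base row: normalized protocol name -> risk class.

    ``metadata`` documents the protocol's eligibility criteria; it is never
    consulted by classification.
    """

    name: str
    risk: RiskLabel
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.risk not in (RiskLabel.SR, RiskLabel.HR):
            raise ValueError(f"protocol risk must be SR or HR, got {self.risk}")


@dataclass
class ProtocolTable:
    entries: dict[str, ProtocolEntry]
    generic_names: frozenset[str] = GENERIC_NAMES

    def __len__(self) -> int:
        return len(self.entries)

    def is_generic(self, raw_name: str) -> bool:
        return normalize_protocol_name(raw_name) in self.generic_names


def normalize_protocol_name(raw: str) -> str:
    """Canonicalize a protocol name: trim, collapse whitespace, uppercase,
    and strip punctuation variants so that "AALL-0331" == "aall0331"."""
    s = _PUNCT_RE.sub("", raw)
    s = _WS_RE.sub(" ", s).strip().upper()
    if not s:
        raise ValueError(f"protocol name empty after normalization: {raw!r}")
    return s


def select_protocol(
    records: Sequence[ProtocolRecord],
) -> Optional[ProtocolRecord]:
    """Disambiguate multiple protocol records for one patient.

    Considers the earliest record plus any record starting within 28 days of
    it; specific beats generic; among specific candidates the latest start
    date wins (ties broken by normalized name, with a warning).  Records
    starting more than 28 days after the first are ignored.  Returns None
    for an empty list.  The result is invariant to input order.
    """
    if not records:
        return None
    ordered = sorted(
        records, key=lambda r: (r.start_date, normalize_protocol_name(r.protocol_name))
    )
    first = ordered[0]
    window = [
        r
        for r in ordered
        if (r.start_date - first.start_date).days <= PROTOCOL_WINDOW_DAYS
    ]
    specific = [r for r in window if r.is_specific]
    pool = specific if specific else window
    best = max(
        pool, key=lambda r: (r.start_date, normalize_protocol_name(r.protocol_name))
    )
    ties = [
        r
        for r in pool
        if r.start_date == best.start_date and r is not best
    ]
    if ties:
        logger.warning(
            "patient %s: %d protocols share start date %s; kept %s by name order",
            best.patient_id, len(ties) + 1, best.start_date, best.protocol_name,
        )
    return best


def protocol_risk(name: str, table: ProtocolTable) -> str:
    """Risk class for a normalized protocol name: 'SR', 'HR' or 'unknown'."""
    entry = table.entries.get(name)
    return entry.risk.value if entry is not None else "unknown"


def classify_registry(
    age_years: float,
    selected: Optional[ProtocolRecord],
    table: ProtocolTable,
    *,
    fallback_age_only: bool = False,
) -> RiskCall:
    """Registry-based risk call from age at diagnosis and selected protocol.

    Children <1 or >=10 years at diagnosis are high risk regardless of
    protocol.  Otherwise the protocol's risk class decides.  When the
    protocol is missing or unknown and age is 1-9, the patient is
    unclassifiable unless ``fallback_age_only`` is set, in which case age
    alone (here necessarily standard risk) is used.
    """
    if age_years < 0:
        raise ValueError("age_years must be non-negative")
    if age_years < 1.0 or age_years >= 10.0:
        return RiskCall(RiskLabel.HR, RiskSource.REGISTRY)
    risk = "unknown"
    if selected is not None:
        risk = protocol_risk(normalize_protocol_name(selected.protocol_name), table)
    if risk == "HR":
        return RiskCall(RiskLabel.HR, RiskSource.REGISTRY)
    if risk == "SR":
        return RiskCall(RiskLabel.SR, RiskSource.REGISTRY)
    if fallback_age_only:
        return RiskCall(RiskLabel.SR, RiskSource.REGISTRY)
    return RiskCall(RiskLabel.UNCLASSIFIABLE, RiskSource.REGISTRY)


def classify_cohort_registry(
    cohort: Iterable,
    protocol_records: Iterable[ProtocolRecord],
    table: ProtocolTable,
    *,
    fallback_age_only: bool = False,
) -> list[tuple[str, RiskCall]]:
    """Registry calls for a cohort of PatientRecords plus protocol records."""
    by_patient: dict[str, list[ProtocolRecord]] = {}
    for rec in protocol_records:
        by_patient.setdefault(rec.patient_id, []).append(rec)
    calls = []
    for p in cohort:
        selected = select_protocol(by_patient.get(p.patient_id, []))
        calls.append(
            (
                p.patient_id,
                classify_registry(
                    p.age_years, selected, table, fallback_age_only=fallback_age_only
                ),
            )
        )
    return calls


_META_COLUMNS = ("lineage", "age_range", "wbc_range", "genetics", "other")


def _entries_from_frame(df: pd.DataFrame) -> dict[str, ProtocolEntry]:
    entries: dict[str, ProtocolEntry] = {}
    for _, row in df.iterrows():
        name = normalize_protocol_name(str(row["name"]))
        if name in entries:
            raise ValueError(f"duplicate protocol name after normalization: {name}")
        risk_raw = str(row["risk"]).strip().upper()
        if risk_raw not in ("SR", "HR"):
            raise ValueError(f"protocol {name}: risk must be SR or HR, got {risk_raw!r}")
        metadata = {
            c: str(row[c])
            for c in _META_COLUMNS
            if c in df.columns and pd.notna(row[c]) and str(row[c]).strip()
        }
        entries[name] = ProtocolEntry(name, RiskLabel(risk_raw), metadata)
    return entries


def load_protocol_table(path: Optional[str | Path] = None) -> ProtocolTable:
    """Load the protocol knowledge base.

    With no argument, returns the built-in sixteen-protocol table.  A user
    file (same CSV schema: name, risk, optional metadata columns) extends
    the built-in table; overriding a built-in risk assignment is applied
    with a logged warning.
    """
    with resources.files("riskproxy.data").joinpath("protocol_table.csv").open() as fh:
        builtin = _entries_from_frame(pd.read_csv(fh))
    if path is None:
        return ProtocolTable(entries=builtin)
    user = _entries_from_frame(pd.read_csv(path))
    merged = dict(builtin)
    for name, entry in user.items():
        if name in merged and merged[name].risk != entry.risk:
            logger.warning(
                "protocol table override: %s %s -> %s",
                name, merged[name].risk.value, entry.risk.value,
            )
        merged[name] = entry
    return ProtocolTable(entries=merged)
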