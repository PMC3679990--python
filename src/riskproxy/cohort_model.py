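"""Domain types and CSV IO for patient cohorts and protocol records.

The cohort model captures the diagnosis-time disease features used by
risk-stratification algorithms in childhood acute lymphoblastic leukemia
(ALL): age, presenting white blood cell count (WBC), blast lineage
(immunophenotype), leukemia cytogenetics, and end-of-induction minimal
residual disease (MRD).  It also carries the study-eligibility flags
(residency, active treatment, early transfer, second malignancy) and a
registry-linkage flag, so that an eligibility cascade can be applied and
audited reproducibly.

All files are UTF-8 comma-delimited CSV with ISO-8601 dates.  Enum
vocabularies are matched case-insensitively and accept the common clinical
spellings (e.g. ``t(9;22)``, ``11q23``).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "Immunophenotype",
    "Cytogenetics",
    "MRDStatus",
    "RiskLabel",
    "RiskSource",
    "RiskCall",
    "PatientRecord",
    "ProtocolRecord",
    "CohortAudit",
    "CohortReadError",
    "read_cohort",
    "write_cohort",
    "read_protocol_records",
    "write_protocol_records",
    "apply_eligibility",
    "write_calls",
    "read_calls",
    "EXCLUSION_REASONS",
]


class Immunophenotype(str, Enum):
    B = "B"
    T = "T"
    MISSING = "missing"


class Cytogenetics(str, Enum):
    MLL_REARRANGEMENT = "MLL_rearrangement"
    T9_22 = "t9_22"
    HYPODIPLOIDY = "hypodiploidy"
    HYPERDIPLOIDY = "hyperdiploidy"
    T12_21 = "t12_21"
    T1_19 = "t1_19"
    NO_SPECIFIC_LESION = "no_specific_lesion"
    MISSING = "missing"


class MRDStatus(str, Enum):
    NEGATIVE = "negative"
    POSITIVE = "positive"
    DIED_BEFORE_TEST = "died_before_test"
    NOT_PERFORMED = "not_performed"


class RiskLabel(str, Enum):
    SR = "SR"
    HR = "HR"
    UNCLASSIFIABLE = "unclassifiable"


class RiskSource(str, Enum):
    BIOLOGY_1 = "biology_1"
    BIOLOGY_2 = "biology_2"
    BIOLOGY_3 = "biology_3"
    BIOLOGY_4 = "biology_4"
    REGISTRY = "registry"


@dataclass(frozen=True)
class RiskCall:
    """A standard-risk / high-risk / unclassifiable label with provenance."""

    label: RiskLabel
    source: RiskSource

    def __post_init__(self) -> None:
        # Biology algorithms treat missing data as non-informative and always
        # emit SR or HR; only the registry algorithm may fail to classify.
        if (
            self.label is RiskLabel.UNCLASSIFIABLE
            and self.source is not RiskSource.REGISTRY
        ):
            raise ValueError(
                "unclassifiable is only permitted for the registry source, "
                f"got source={self.source.value}"
            )


# Accepted spellings for each enum, matched after lower-casing and stripping.
_IMMUNO_ALIASES = {
    "b": Immunophenotype.B,
    "b-cell": Immunophenotype.B,
    "b cell": Immunophenotype.B,
    "t": Immunophenotype.T,
    "t-cell": Immunophenotype.T,
    "t cell": Immunophenotype.T,
    "missing": Immunophenotype.MISSING,
    "": Immunophenotype.MISSING,
}

_CYTO_ALIASES = {
    "mll_rearrangement": Cytogenetics.MLL_REARRANGEMENT,
    "mll rearrangement": Cytogenetics.MLL_REARRANGEMENT,
    "mll": Cytogenetics.MLL_REARRANGEMENT,
    "11q23": Cytogenetics.MLL_REARRANGEMENT,
    "t9_22": Cytogenetics.T9_22,
    "t(9;22)": Cytogenetics.T9_22,
    "t(9;22) (bcr-abl)": Cytogenetics.T9_22,
    "bcr-abl": Cytogenetics.T9_22,
    "hypodiploidy": Cytogenetics.HYPODIPLOIDY,
    "hyperdiploidy": Cytogenetics.HYPERDIPLOIDY,
    "t12_21": Cytogenetics.T12_21,
    "t(12;21)": Cytogenetics.T12_21,
    "t(12;21) (tel-aml)": Cytogenetics.T12_21,
    "tel-aml": Cytogenetics.T12_21,
    "t1_19": Cytogenetics.T1_19,
    "t(1;19)": Cytogenetics.T1_19,
    "t(1;19) (e2a-pbx)": Cytogenetics.T1_19,
    "e2a-pbx": Cytogenetics.T1_19,
    "no_specific_lesion": Cytogenetics.NO_SPECIFIC_LESION,
    "no specific lesion": Cytogenetics.NO_SPECIFIC_LESION,
    "none": Cytogenetics.NO_SPECIFIC_LESION,
    "missing": Cytogenetics.MISSING,
    "": Cytogenetics.MISSING,
}

_MRD_ALIASES = {
    "negative": MRDStatus.NEGATIVE,
    "positive": MRDStatus.POSITIVE,
    "died_before_test": MRDStatus.DIED_BEFORE_TEST,
    "died before test": MRDStatus.DIED_BEFORE_TEST,
    "died prior to test": MRDStatus.DIED_BEFORE_TEST,
    "not_performed": MRDStatus.NOT_PERFORMED,
    "not performed": MRDStatus.NOT_PERFORMED,
}

_BOOL_ALIASES = {
    "true": True, "1": True, "yes": True, "y": True,
    "false": False, "0": False, "no": False, "n": False,
}


def _parse_enum(raw: object, aliases: Mapping[str, Enum], what: str) -> Enum:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        key = ""
    else:
        key = str(raw).strip().lower()
    try:
        return aliases[key]
    except KeyError:
        raise ValueError(f"unrecognized {what} value: {raw!r}") from None


def _parse_bool(raw: object, what: str) -> bool:
    if isinstance(raw, bool):
        return raw
    key = str(raw).strip().lower()
    try:
        return _BOOL_ALIASES[key]
    except KeyError:
        raise ValueError(f"unrecognized boolean for {what}: {raw!r}") from None


@dataclass
class PatientRecord:
    """One child's diagnosis-time disease features plus eligibility flags.

    ``age_years`` is a real number of years at diagnosis and ``wbc`` the
    presenting white-cell count in units of 10^9 cells/L.
    """

    patient_id: str
    age_years: float
    wbc: float
    immunophenotype: Immunophenotype
    cytogenetics: Cytogenetics
    mrd: MRDStatus
    diagnosis_date: date
    ontario_resident: bool = True
    treatment_pursued: bool = True
    transferred_within_month: bool = False
    second_malignancy: bool = False
    linked_to_registry: bool = True
    sex: Optional[str] = None  # optional, used by no algorithm

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise ValueError(f"age_years must be >= 0, got {self.age_years}")
        if self.wbc < 0:
            raise ValueError(f"wbc must be >= 0, got {self.wbc}")
        if not isinstance(self.immunophenotype, Immunophenotype):
            raise TypeError("immunophenotype must be an Immunophenotype")
        if not isinstance(self.cytogenetics, Cytogenetics):
            raise TypeError("cytogenetics must be a Cytogenetics")
        if not isinstance(self.mrd, MRDStatus):
            raise TypeError("mrd must be an MRDStatus")


@dataclass(frozen=True)
class ProtocolRecord:
    """A treatment-protocol assignment event from the registry side.

    ``is_specific`` distinguishes a named cooperative-group protocol
    (e.g. AALL0331) from a generic descriptor such as "three drug induction".
    """

    patient_id: str
    protocol_name: str
    start_date: date
    is_specific: bool = True

    def __post_init__(self) -> None:
        if not self.protocol_name.strip():
            raise ValueError("protocol_name must be non-empty")


EXCLUSION_REASONS = (
    "non_resident",
    "transferred",
    "second_malignancy",
    "no_treatment",
)


@dataclass
class CohortAudit:
    """Bookkeeping for the eligibility cascade.

    Reports the analyzed fraction against both the pre-exclusion total and
    the post-exclusion (linkage-eligible) denominator, since both are
    legitimate summaries of the cascade.
    """

    n_total: int
    n_excluded_by_reason: dict[str, int] = field(default_factory=dict)
    n_unlinked: int = 0
    n_analyzed: int = 0

    @property
    def n_excluded(self) -> int:
        return sum(self.n_excluded_by_reason.values())

    @property
    def n_eligible(self) -> int:
        return self.n_total - self.n_excluded

    @property
    def analyzed_pct_of_total(self) -> float:
        return 100.0 * self.n_analyzed / self.n_total if self.n_total else 0.0

    @property
    def analyzed_pct_of_eligible(self) -> float:
        return 100.0 * self.n_analyzed / self.n_eligible if self.n_eligible else 0.0

    def validate(self) -> None:
        if self.n_analyzed != self.n_total - self.n_excluded - self.n_unlinked:
            raise ValueError("audit counts do not partition the cohort")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_total": self.n_total,
            "n_excluded_by_reason": dict(self.n_excluded_by_reason),
            "n_excluded": self.n_excluded,
            "n_eligible": self.n_eligible,
            "n_unlinked": self.n_unlinked,
            "n_analyzed": self.n_analyzed,
            "analyzed_pct_of_total": round(self.analyzed_pct_of_total, 1),
            "analyzed_pct_of_eligible": round(self.analyzed_pct_of_eligible, 1),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


class CohortReadError(ValueError):
    """Raised when a cohort file cannot be parsed in strict mode."""

    def __init__(self, message: str, row_errors: Optional[list[str]] = None):
        super().__init__(message)
        self.row_errors = row_errors or []


_COHORT_COLUMNS = [
    "patient_id", "age_years", "wbc", "immunophenotype", "cytogenetics",
    "mrd", "diagnosis_date", "ontario_resident", "treatment_pursued",
    "transferred_within_month", "second_malignancy", "linked_to_registry",
]


def read_cohort(path: str | Path, *, lenient: bool = False) -> list[PatientRecord]:
    """Read a cohort CSV into validated :class:`PatientRecord` objects.

    In strict mode (default) any unparseable row aborts the read with a
    :class:`CohortReadError` listing every bad row; with ``lenient=True``
    bad rows are dropped and reported on the error's ``row_errors`` only if
    all rows fail.  A missing mandatory column is always a hard error.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in _COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortReadError(f"cohort file missing mandatory column(s): {missing}")

    records: list[PatientRecord] = []
    row_errors: list[str] = []
    for idx, row in df.iterrows():
        try:
            records.append(
                PatientRecord(
                    patient_id=str(row["patient_id"]),
                    age_years=float(row["age_years"]),
                    wbc=float(row["wbc"]),
                    immunophenotype=_parse_enum(
                        row["immunophenotype"], _IMMUNO_ALIASES, "immunophenotype"
                    ),
                    cytogenetics=_parse_enum(
                        row["cytogenetics"], _CYTO_ALIASES, "cytogenetics"
                    ),
                    mrd=_parse_enum(row["mrd"], _MRD_ALIASES, "mrd"),
                    diagnosis_date=date.fromisoformat(str(row["diagnosis_date"])),
                    ontario_resident=_parse_bool(row["ontario_resident"], "ontario_resident"),
                    treatment_pursued=_parse_bool(row["treatment_pursued"], "treatment_pursued"),
                    transferred_within_month=_parse_bool(
                        row["transferred_within_month"], "transferred_within_month"
                    ),
                    second_malignancy=_parse_bool(row["second_malignancy"], "second_malignancy"),
                    linked_to_registry=_parse_bool(row["linked_to_registry"], "linked_to_registry"),
                    sex=(str(row["sex"]) if "sex" in df.columns and pd.notna(row.get("sex")) else None),
                )
            )
        except (ValueError, TypeError) as exc:
            row_errors.append(f"row {idx + 2}: {exc}")  # +2: header + 1-based
    if row_errors and not lenient:
        raise CohortReadError(
            f"{len(row_errors)} row(s) failed to parse", row_errors
        )
    return records


def write_cohort(cohort: Iterable[PatientRecord], path: str | Path) -> None:
    """Write patient records to CSV in the canonical column order."""
    rows = []
    for p in cohort:
        d = asdict(p)
        d["immunophenotype"] = p.immunophenotype.value
        d["cytogenetics"] = p.cytogenetics.value
        d["mrd"] = p.mrd.value
        d["diagnosis_date"] = p.diagnosis_date.isoformat()
        rows.append(d)
    cols = _COHORT_COLUMNS + ["sex"]
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, index=False)


def read_protocol_records(path: str | Path) -> list[ProtocolRecord]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    needed = ["patient_id", "protocol_name", "start_date", "is_specific"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise CohortReadError(f"protocol file missing mandatory column(s): {missing}")
    return [
        ProtocolRecord(
            patient_id=str(r["patient_id"]),
            protocol_name=str(r["protocol_name"]),
            start_date=date.fromisoformat(str(r["start_date"])),
            is_specific=_parse_bool(r["is_specific"], "is_specific"),
        )
        for _, r in df.iterrows()
    ]


def write_protocol_records(records: Iterable[ProtocolRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "protocol_name": r.protocol_name,
                "start_date": r.start_date.isoformat(),
                "is_specific": r.is_specific,
            }
            for r in records
        ],
        columns=["patient_id", "protocol_name", "start_date", "is_specific"],
    )
    df.to_csv(path, index=False)


def apply_eligibility(
    cohort: Sequence[PatientRecord],
) -> tuple[list[PatientRecord], CohortAudit]:
    """Apply the study eligibility cascade and return the analyzed cohort.

    Filters are applied in a fixed order so that tallies are reproducible:
    residency, early transfer, second malignancy, no active treatment, then
    registry linkage.  Each patient is counted once, under the first filter
    it fails (or as analyzed).
    """
    tallies: Counter[str] = Counter()
    n_unlinked = 0
    kept: list[PatientRecord] = []
    for p in cohort:
        if not p.ontario_resident:
            tallies["non_resident"] += 1
        elif p.transferred_within_month:
            tallies["transferred"] += 1
        elif p.second_malignancy:
            tallies["second_malignancy"] += 1
        elif not p.treatment_pursued:
            tallies["no_treatment"] += 1
        elif not p.linked_to_registry:
            n_unlinked += 1
        else:
            kept.append(p)
    audit = CohortAudit(
        n_total=len(cohort),
        n_excluded_by_reason={r: tallies.get(r, 0) for r in EXCLUSION_REASONS},
        n_unlinked=n_unlinked,
        n_analyzed=len(kept),
    )
    audit.validate()
    return kept, audit


_CALL_SOURCES = [s.value for s in RiskSource]


def write_calls(
    calls: Mapping[str, Mapping[RiskSource, Optional[RiskCall]]] | Sequence[tuple],
    path: str | Path,
) -> None:
    """Write per-patient risk calls (all five sources) to CSV.

    Accepts either a mapping ``patient_id -> {source: RiskCall | None}`` or a
    sequence of ``(patient_id, {source: call})`` pairs.  Duplicate patient
    ids are a hard error; absent calls are written as empty cells.
    """
    if isinstance(calls, Mapping):
        items = list(calls.items())
    else:
        items = list(calls)
    seen: set[str] = set()
    rows = []
    for patient_id, by_source in items:
        if patient_id in seen:
            raise ValueError(f"duplicate patient_id in calls: {patient_id}")
        seen.add(patient_id)
        row: dict[str, str] = {"patient_id": patient_id}
        for src in RiskSource:
            call = by_source.get(src) if by_source else None
            row[src.value] = call.label.value if call is not None else ""
        rows.append(row)
    df = pd.DataFrame(rows, columns=["patient_id"] + _CALL_SOURCES)
    df.to_csv(path, index=False)


def read_calls(path: str | Path) -> dict[str, dict[RiskSource, Optional[RiskCall]]]:
    """Inverse of :func:`write_calls`."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out: dict[str, dict[RiskSource, Optional[RiskCall]]] = {}
    for _, r in df.iterrows():
        by_source: dict[RiskSource, Optional[RiskCall]] = {}
        for src in RiskSource:
            raw = r.get(src.value, "")
            by_source[src] = (
                RiskCall(RiskLabel(raw), src) if raw else None
            )
        out[str(r["patient_id"])] = by_source
    return out
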