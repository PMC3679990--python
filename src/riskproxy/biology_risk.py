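"""Biology-based risk algorithms for childhood ALL.

Four nested algorithms assign a two-level risk stratum (standard risk, SR,
vs high risk, HR) from chart-review disease features.  Algorithm 1 is the
NCI/Rome criterion (age and presenting WBC); each subsequent level adds one
high-risk classifier, in the fixed order:

    1. age + WBC        SR iff 1 <= age < 10 years and WBC < 50 x10^9/L
    2. + immunophenotype  T lineage is high risk
    3. + cytogenetics     t(9;22), hypodiploidy, any 11q23/MLL rearrangement
    4. + MRD              >= 0.01% end-of-induction residual blasts (positive)

Within every level the presence of any high-risk feature places the patient
in the high-risk stratum.  A missing prognosticator is non-informative: it
can never, by itself, make a patient high risk, so the biology algorithms
always return SR or HR and never "unclassifiable".
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

from .cohort_model import (
    Cytogenetics,
    Immunophenotype,
    MRDStatus,
    PatientRecord,
    RiskCall,
    RiskLabel,
    RiskSource,
)

__all__ = [
    "FEATURE_GROUPS",
    "features_for_level",
    "classify_nci",
    "high_risk_cytogenetics",
    "classify_biology",
    "classify_cohort_biology",
    "BIOLOGY_SOURCES",
]

# Feature groups in the order the algorithm levels add them.
FEATURE_GROUPS = ("age_wbc", "immunophenotype", "cytogenetics", "mrd")

BIOLOGY_SOURCES = {
    1: RiskSource.BIOLOGY_1,
    2: RiskSource.BIOLOGY_2,
    3: RiskSource.BIOLOGY_3,
    4: RiskSource.BIOLOGY_4,
}

_HIGH_RISK_CYTO = frozenset(
    {
        Cytogenetics.T9_22,
        Cytogenetics.HYPODIPLOIDY,
        Cytogenetics.MLL_REARRANGEMENT,
    }
)


def features_for_level(level: int) -> tuple[str, ...]:
    """Feature groups used by algorithm ``level`` (the first ``level`` groups)."""
    _check_level(level)
    return FEATURE_GROUPS[:level]


def _check_level(level: int) -> None:
    if level not in BIOLOGY_SOURCES:
        raise ValueError(f"algorithm level must be in 1..4, got {level}")


def classify_nci(age_years: float, wbc: float) -> RiskCall:
    """NCI/Rome criterion: SR iff age in [1, 10) years and WBC < 50 x10^9/L.

    Interval conventions are half-open: "1-9 years" means 1.0 <= age < 10.0,
    and a WBC of exactly 50 is high risk ("<50" defines standard risk).
    """
    if age_years < 0 or wbc < 0:
        raise ValueError("age_years and wbc must be non-negative")
    sr = (1.0 <= age_years < 10.0) and (wbc < 50.0)
    return RiskCall(RiskLabel.SR if sr else RiskLabel.HR, RiskSource.BIOLOGY_1)


def high_risk_cytogenetics(cyto: Cytogenetics) -> bool:
    """True for t(9;22), hypodiploidy (<45 chromosomes) and MLL/11q23 lesions.

    Standard-risk lesions, "no specific lesion" and missing cytogenetics are
    all non-informative (False).
    """
    return cyto in _HIGH_RISK_CYTO


def classify_biology(p: PatientRecord, level: int) -> RiskCall:
    """Classify one patient with the biology algorithm at ``level`` (1-4)."""
    _check_level(level)
    hr = classify_nci(p.age_years, p.wbc).label is RiskLabel.HR
    if level >= 2:
        hr = hr or p.immunophenotype is Immunophenotype.T
    if level >= 3:
        hr = hr or high_risk_cytogenetics(p.cytogenetics)
    if level >= 4:
        # not_performed and died_before_test are non-informative
        hr = hr or p.mrd is MRDStatus.POSITIVE
    return RiskCall(RiskLabel.HR if hr else RiskLabel.SR, BIOLOGY_SOURCES[level])


def classify_cohort_biology(
    cohort: Iterable[PatientRecord], level: int
) -> tuple[list[tuple[str, RiskCall]], Counter]:
    """Classify a whole cohort; returns per-patient calls and SR/HR tallies."""
    calls = [(p.patient_id, classify_biology(p, level)) for p in cohort]
    tallies = Counter(call.label.value for _, call in calls)
    tallies.setdefault("SR", 0)
    tallies.setdefault("HR", 0)
    return calls, tallies
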