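"""Agreement statistics between the registry and biology risk classifiers.

The registry-based classifier is validated against each biology-based
algorithm as the reference standard (criterion validity).  For a 2x2
cross-classification with rows = registry call and columns = biology call,

    a = both HR    b = registry HR / biology SR
    c = registry SR / biology HR    d = both SR

Cohen's kappa corrects observed agreement for chance:

    po = (a + d) / n
    pe = ((a+b)(a+c) + (c+d)(b+d)) / n^2
    kappa = (po - pe) / (1 - pe)

The default standard error is the simple large-sample form
``sqrt(po (1-po) / (n (1-pe)^2))`` with a 1.96 normal quantile for the 95%
confidence interval; the Fleiss-Cohen-Everitt corrected SE is available as
an option.  Kappa magnitudes are labelled with the Landis-Koch bands
(0.00-0.20 slight, 0.21-0.40 fair, 0.41-0.60 moderate, 0.61-0.80
substantial, 0.81-1.00 almost perfect).

Diagnostic metrics treat registry HR as the positive test: sensitivity
a/(a+c), specificity d/(b+d), PPV a/(a+b), NPV d/(c+d).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional, Sequence

from .cohort_model import RiskCall, RiskLabel, RiskSource

__all__ = [
    "ContingencyTable2x2",
    "KappaInterpretation",
    "AgreementResult",
    "crosstab",
    "cohen_kappa",
    "diagnostic_metrics",
    "interpret_kappa",
    "agreement_report",
]

logger = logging.getLogger(__name__)

Z_95 = 1.96


class KappaInterpretation(str, Enum):
    SLIGHT = "slight"
    FAIR = "fair"
    MODERATE = "moderate"
    SUBSTANTIAL = "substantial"
    ALMOST_PERFECT = "almost_perfect"


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Registry (rows) vs biology (columns) cross-classification counts."""

    n_hr_hr: int  # registry HR, biology HR
    n_hr_sr: int  # registry HR, biology SR
    n_sr_hr: int  # registry SR, biology HR
    n_sr_sr: int  # registry SR, biology SR

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    @property
    def n(self) -> int:
        return self.n_hr_hr + self.n_hr_sr + self.n_sr_hr + self.n_sr_sr

    def transpose(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(
            self.n_hr_hr, self.n_sr_hr, self.n_hr_sr, self.n_sr_sr
        )

    def scaled(self, factor: int) -> "ContingencyTable2x2":
        return ContingencyTable2x2(
            self.n_hr_hr * factor,
            self.n_hr_sr * factor,
            self.n_sr_hr * factor,
            self.n_sr_sr * factor,
        )


@dataclass
class AgreementResult:
    kappa: float
    se_kappa: float
    ci_low: float
    ci_high: float
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    interpretation: KappaInterpretation
    table: ContingencyTable2x2

    def to_dict(self) -> dict:
        return {
            "kappa": self.kappa,
            "se_kappa": self.se_kappa,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "interpretation": self.interpretation.value,
            "table": {
                "n_hr_hr": self.table.n_hr_hr,
                "n_hr_sr": self.table.n_hr_sr,
                "n_sr_hr": self.table.n_sr_hr,
                "n_sr_sr": self.table.n_sr_sr,
            },
        }


def crosstab(
    registry_calls: Mapping[str, RiskCall] | Sequence[tuple[str, RiskCall]],
    biology_calls: Mapping[str, RiskCall] | Sequence[tuple[str, RiskCall]],
    *,
    unclassifiable: str = "exclude",
) -> tuple[ContingencyTable2x2, dict[str, list[str]]]:
    """Cross-classify registry against biology calls for a common patient set.

    Returns the 2x2 table and the discordant patient ids per off-diagonal
    cell (keys ``hr_sr`` and ``sr_hr``).  Patients the registry could not
    classify are excluded (the default policy) and reported under the
    ``unclassifiable`` key; with ``unclassifiable='error'`` they raise.
    The two call sets must cover exactly the same patients.
    """
    reg = dict(registry_calls)
    bio = dict(biology_calls)
    if set(reg) != set(bio):
        only_r = sorted(set(reg) - set(bio))[:5]
        only_b = sorted(set(bio) - set(reg))[:5]
        raise ValueError(
            f"mismatched patient sets: {len(reg)} registry vs {len(bio)} biology "
            f"(registry-only e.g. {only_r}, biology-only e.g. {only_b})"
        )
    counts = {"hr_hr": 0, "hr_sr": 0, "sr_hr": 0, "sr_sr": 0}
    ids: dict[str, list[str]] = {"hr_sr": [], "sr_hr": [], "unclassifiable": []}
    for pid in sorted(reg):
        r, b = reg[pid].label, bio[pid].label
        if b is RiskLabel.UNCLASSIFIABLE:
            raise ValueError(f"biology call unclassifiable for {pid}")
        if r is RiskLabel.UNCLASSIFIABLE:
            if unclassifiable == "error":
                raise ValueError(f"registry call unclassifiable for {pid}")
            ids["unclassifiable"].append(pid)
            continue
        cell = f"{r.value.lower()}_{b.value.lower()}"
        counts[cell] += 1
        if cell in ("hr_sr", "sr_hr"):
            ids[cell].append(pid)
    table = ContingencyTable2x2(
        counts["hr_hr"], counts["hr_sr"], counts["sr_hr"], counts["sr_sr"]
    )
    return table, ids


def cohen_kappa(
    t: ContingencyTable2x2, *, se_method: str = "simple"
) -> tuple[float, float, float, float]:
    """Cohen's kappa with large-sample SE and 95% CI for a 2x2 table.

    ``se_method='simple'`` uses sqrt(po(1-po) / (n(1-pe)^2));
    ``se_method='fleiss'`` uses the Fleiss-Cohen-Everitt corrected variance.
    """
    n = t.n
    if n == 0:
        raise ValueError("empty table: no patients to compare")
    a, b, c, d = t.n_hr_hr, t.n_hr_sr, t.n_sr_hr, t.n_sr_sr
    po = (a + d) / n
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
    if pe >= 1.0:
        raise ValueError(
            "degenerate marginals: both raters constant (pe = 1), kappa undefined"
        )
    kappa = (po - pe) / (1 - pe)
    if se_method == "simple":
        se = math.sqrt(po * (1 - po) / (n * (1 - pe) ** 2))
    elif se_method == "fleiss":
        se = _fleiss_se(t, kappa, pe)
    else:
        raise ValueError(f"unknown se_method: {se_method!r}")
    return kappa, se, kappa - Z_95 * se, kappa + Z_95 * se


def _fleiss_se(t: ContingencyTable2x2, kappa: float, pe: float) -> float:
    """Fleiss-Cohen-Everitt asymptotic SE of kappa-hat for a 2x2 table."""
    n = t.n
    p = [
        [t.n_hr_hr / n, t.n_hr_sr / n],
        [t.n_sr_hr / n, t.n_sr_sr / n],
    ]
    row = [p[0][0] + p[0][1], p[1][0] + p[1][1]]
    col = [p[0][0] + p[1][0], p[0][1] + p[1][1]]
    term1 = sum(
        p[i][i] * (1 - (row[i] + col[i]) * (1 - kappa)) ** 2 for i in range(2)
    )
    term2 = (1 - kappa) ** 2 * sum(
        p[i][j] * (col[i] + row[j]) ** 2 for i in range(2) for j in range(2) if i != j
    )
    term3 = (kappa - pe * (1 - kappa)) ** 2
    var = (term1 + term2 - term3) / (n * (1 - pe) ** 2)
    return math.sqrt(max(var, 0.0))


def diagnostic_metrics(
    t: ContingencyTable2x2,
) -> tuple[Optional[float], Optional[float], Optional[float], Optional[float]]:
    """(sensitivity, specificity, PPV, NPV) with registry HR as the positive
    test and the biology call as the reference standard.

    A metric whose denominator is zero is returned as None with a warning
    rather than raising.
    """
    a, b, c, d = t.n_hr_hr, t.n_hr_sr, t.n_sr_hr, t.n_sr_sr

    def ratio(num: int, den: int, name: str) -> Optional[float]:
        if den == 0:
            logger.warning("%s undefined: zero denominator", name)
            return None
        return num / den

    return (
        ratio(a, a + c, "sensitivity"),
        ratio(d, b + d, "specificity"),
        ratio(a, a + b, "ppv"),
        ratio(d, c + d, "npv"),
    )


def interpret_kappa(k: float) -> KappaInterpretation:
    """Landis-Koch band for a kappa value.

    The bands are stated to two decimals (0.00-0.20, 0.21-0.40, ...); values
    falling in a gap between bands (e.g. 0.205) are assigned to the upper
    band.  Negative values are reported as slight with a warning.
    """
    if k > 1.0:
        raise ValueError(f"kappa cannot exceed 1, got {k}")
    if k < 0:
        logger.warning("kappa %.3f < 0 (worse than chance); reporting slight", k)
        return KappaInterpretation.SLIGHT
    if k <= 0.20:
        return KappaInterpretation.SLIGHT
    if k <= 0.40:
        return KappaInterpretation.FAIR
    if k <= 0.60:
        return KappaInterpretation.MODERATE
    if k <= 0.80:
        return KappaInterpretation.SUBSTANTIAL
    return KappaInterpretation.ALMOST_PERFECT


def agreement_report(
    registry_calls: Mapping[str, RiskCall] | Sequence[tuple[str, RiskCall]],
    biology_calls_by_level: Mapping[int, Mapping[str, RiskCall] | Sequence[tuple[str, RiskCall]]],
    *,
    discordance_reasons: Optional[Mapping[str, str]] = None,
    se_method: str = "simple",
) -> dict:
    """Full agreement report: one AgreementResult per biology level.

    ``discordance_reasons`` (patient id -> injected mechanism label) is
    attached to the discordant-case listing when the cohort is synthetic and
    carries ground truth.  Degenerate levels (e.g. constant marginals on a
    tiny cohort) are reported as errors without aborting the other levels.
    """
    report: dict = {"levels": {}, "discordant": {}}
    for level in sorted(biology_calls_by_level):
        try:
            table, ids = crosstab(registry_calls, biology_calls_by_level[level])
            kappa, se, lo, hi = cohen_kappa(table, se_method=se_method)
            sens, spec, ppv, npv = diagnostic_metrics(table)
            result = AgreementResult(
                kappa=kappa,
                se_kappa=se,
                ci_low=lo,
                ci_high=hi,
                sensitivity=sens,
                specificity=spec,
                ppv=ppv,
                npv=npv,
                interpretation=interpret_kappa(kappa),
                table=table,
            )
            report["levels"][level] = result
            listing = []
            for cell in ("hr_sr", "sr_hr"):
                for pid in ids[cell]:
                    entry = {"patient_id": pid, "cell": cell}
                    if discordance_reasons and pid in discordance_reasons:
                        entry["reason"] = discordance_reasons[pid]
                    listing.append(entry)
            report["discordant"][level] = listing
            if ids["unclassifiable"]:
                report.setdefault("unclassifiable", {})[level] = ids["unclassifiable"]
        except ValueError as exc:
            report["levels"][level] = {"error": str(exc)}
            report["discordant"][level] = []
    return report
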