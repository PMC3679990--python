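"""End-to-end pipeline: cohort in, audit + calls + agreement report out.

The pipeline is a pure function of its inputs and configuration: given the
same cohort, protocol records and options it writes bit-identical artifacts.
Stages: eligibility cascade -> biology algorithms 1-4 -> protocol selection
and registry classification -> cross-tabulation and agreement statistics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .agreement import AgreementResult, agreement_report
from .biology_risk import BIOLOGY_SOURCES, classify_cohort_biology
from .cohort_model import (
    PatientRecord,
    ProtocolRecord,
    RiskCall,
    RiskSource,
    apply_eligibility,
    read_cohort,
    read_protocol_records,
    write_calls,
)
from .protocol_registry import (
    ProtocolTable,
    classify_cohort_registry,
    load_protocol_table,
)
from .synthetic_cohort import (
    GeneratorConfig,
    SyntheticPatient,
    build_study_replica,
    generate_cohort,
    summarize_cohort,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one input mode must be selected: file paths, the deterministic
    replica, or the stochastic generator.
    """

    cohort_path: Optional[Path] = None
    protocols_path: Optional[Path] = None
    replica: bool = False
    generate: Optional[GeneratorConfig] = None
    protocol_table_path: Optional[Path] = None
    fallback_age_only: bool = False
    out_dir: Path = Path("results")

    def validate(self) -> None:
        modes = [
            self.cohort_path is not None,
            self.replica,
            self.generate is not None,
        ]
        if sum(modes) != 1:
            raise ValueError(
                "exactly one input mode required: --cohort, --replica or --generate"
            )
        if self.cohort_path is not None and self.protocols_path is None:
            raise ValueError("file mode requires a protocol-records file")


@dataclass
class PipelineResult:
    audit: object
    calls: dict[str, dict[RiskSource, Optional[RiskCall]]]
    report: dict
    summary: pd.DataFrame
    artifacts: dict[str, Path] = field(default_factory=dict)


def _load_inputs(
    cfg: RunConfig,
) -> tuple[list[PatientRecord], list[ProtocolRecord], dict[str, str]]:
    """Returns records, protocol records and ground-truth discordance tags."""
    tags: dict[str, str] = {}
    if cfg.replica or cfg.generate is not None:
        patients: Sequence[SyntheticPatient] = (
            build_study_replica() if cfg.replica else generate_cohort(cfg.generate)
        )
        records = [p.record for p in patients]
        protocols = [pr for p in patients for pr in p.protocols]
        tags = {
            p.record.patient_id: p.injected_discordance_reason
            for p in patients
            if p.injected_discordance_reason
        }
    else:
        records = read_cohort(cfg.cohort_path)
        protocols = read_protocol_records(cfg.protocols_path)
    return records, protocols, tags


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Run the full validation pipeline and write its artifacts.

    Writes under ``cfg.out_dir``: ``audit.json``, ``calls.csv``,
    ``agreement.json``, ``discordant.csv`` and ``summary.csv``.
    """
    cfg.validate()
    records, protocols, tags = _load_inputs(cfg)
    table: ProtocolTable = load_protocol_table(cfg.protocol_table_path)

    analyzed, audit = apply_eligibility(records)
    logger.info(
        "eligibility: %d total, %d excluded %s, %d unlinked, %d analyzed",
        audit.n_total, audit.n_excluded, dict(audit.n_excluded_by_reason),
        audit.n_unlinked, audit.n_analyzed,
    )

    biology_calls: dict[int, dict[str, RiskCall]] = {}
    for level in (1, 2, 3, 4):
        calls, tallies = classify_cohort_biology(analyzed, level)
        biology_calls[level] = dict(calls)
        logger.info("biology algorithm %d: %s", level, dict(tallies))
    registry_calls = dict(
        classify_cohort_registry(
            analyzed, protocols, table, fallback_age_only=cfg.fallback_age_only
        )
    )

    report = agreement_report(
        registry_calls, biology_calls, discordance_reasons=tags or None
    )

    calls_out: dict[str, dict[RiskSource, Optional[RiskCall]]] = {}
    for p in analyzed:
        row: dict[RiskSource, Optional[RiskCall]] = {
            BIOLOGY_SOURCES[lv]: biology_calls[lv][p.patient_id] for lv in (1, 2, 3, 4)
        }
        row[RiskSource.REGISTRY] = registry_calls[p.patient_id]
        calls_out[p.patient_id] = row

    label_calls = {
        lv: {pid: call.label for pid, call in by.items()}
        for lv, by in biology_calls.items()
    }
    summary = summarize_cohort(analyzed, label_calls)

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts = {
        "audit": out / "audit.json",
        "calls": out / "calls.csv",
        "agreement": out / "agreement.json",
        "discordant": out / "discordant.csv",
        "summary": out / "summary.csv",
    }
    audit.to_json(artifacts["audit"])
    write_calls(calls_out, artifacts["calls"])
    serializable = {
        "levels": {
            str(lv): (res.to_dict() if isinstance(res, AgreementResult) else res)
            for lv, res in report["levels"].items()
        },
        "unclassifiable": {
            str(k): v for k, v in report.get("unclassifiable", {}).items()
        },
    }
    artifacts["agreement"].write_text(json.dumps(serializable, indent=2) + "\n")
    disc_rows = [
        {"level": lv, **entry}
        for lv, entries in report["discordant"].items()
        for entry in entries
    ]
    pd.DataFrame(
        disc_rows, columns=["level", "patient_id", "cell", "reason"]
    ).to_csv(artifacts["discordant"], index=False)
    summary.to_csv(artifacts["summary"], index=False)

    return PipelineResult(audit, calls_out, report, summary, artifacts)
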