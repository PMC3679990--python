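"""Synthetic cohorts: replica contract, seed determinism, parameter recovery."""

import math
from collections import Counter

import numpy as np
import pytest

from riskproxy.agreement import crosstab
from riskproxy.biology_risk import high_risk_cytogenetics
from riskproxy.cohort_model import (
    Cytogenetics,
    Immunophenotype,
    MRDStatus,
    RiskCall,
    RiskLabel,
    RiskSource,
    apply_eligibility,
)
from riskproxy.protocol_registry import classify_cohort_registry, load_protocol_table
from riskproxy.synthetic_cohort import (
    DISCORDANCE_MECHANISMS,
    GeneratorConfig,
    build_study_replica,
    generate_cohort,
    summarize_cohort,
    write_cohort_artifacts,
)


def registry_vs_bio3(patients, table):
    analyzed, _ = apply_eligibility([p.record for p in patients])
    by_id = {p.record.patient_id: p for p in patients}
    reg = dict(
        classify_cohort_registry(
            analyzed, [pr for p in patients for pr in p.protocols], table
        )
    )
    bio3 = {
        r.patient_id: RiskCall(by_id[r.patient_id].true_biology[3], RiskSource.BIOLOGY_3)
        for r in analyzed
    }
    return crosstab(reg, bio3)


class TestReplicaContract:
    def test_eligibility_cascade(self, replica_records):
        _, audit = apply_eligibility(replica_records)
        assert audit.n_total == 596
        assert audit.n_excluded == 12
        assert audit.n_unlinked == 5
        assert audit.n_analyzed == 579

    @pytest.mark.parametrize(
        "level,sr,hr",
        [(1, 359, 220), (2, 347, 232), (3, 340, 239), (4, 324, 255)],
    )
    def test_algorithm_marginals(self, replica_patients, level, sr, hr):
        analyzed_ids = {
            r.patient_id for r in apply_eligibility(
                [p.record for p in replica_patients]
            )[0]
        }
        tally = Counter(
            p.true_biology[level].value
            for p in replica_patients
            if p.record.patient_id in analyzed_ids
        )
        assert (tally["SR"], tally["HR"]) == (sr, hr)

    def test_lineage_and_cytogenetics_cells(self, replica_patients):
        analyzed = {
            r.patient_id
            for r in apply_eligibility([p.record for p in replica_patients])[0]
        }
        pts = [p for p in replica_patients if p.record.patient_id in analyzed]
        t_cell = [p for p in pts if p.record.immunophenotype is Immunophenotype.T]
        assert len(t_cell) == 57
        assert sum(p.true_biology[1] is RiskLabel.SR for p in t_cell) == 12
        hr_cyto = Counter(
            p.record.cytogenetics
            for p in pts
            if high_risk_cytogenetics(p.record.cytogenetics)
        )
        assert hr_cyto[Cytogenetics.MLL_REARRANGEMENT] == 19
        assert hr_cyto[Cytogenetics.T9_22] == 10
        assert hr_cyto[Cytogenetics.HYPODIPLOIDY] == 7
        hr_cyto_sr2 = [
            p for p in pts
            if high_risk_cytogenetics(p.record.cytogenetics)
            and p.true_biology[2] is RiskLabel.SR
        ]
        assert len(hr_cyto_sr2) == 7

    def test_mrd_cells(self, replica_patients):
        analyzed = {
            r.patient_id
            for r in apply_eligibility([p.record for p in replica_patients])[0]
        }
        pts = [p for p in replica_patients if p.record.patient_id in analyzed]
        mrd = Counter(p.record.mrd for p in pts)
        assert mrd[MRDStatus.POSITIVE] == 38
        assert mrd[MRDStatus.NOT_PERFORMED] == 277
        assert mrd[MRDStatus.DIED_BEFORE_TEST] == 6
        pos_sr3 = [
            p for p in pts
            if p.record.mrd is MRDStatus.POSITIVE
            and p.true_biology[3] is RiskLabel.SR
        ]
        assert len(pos_sr3) == 16

    def test_registry_discordance_cells(self, replica_patients, protocol_table):
        table, ids = registry_vs_bio3(replica_patients, protocol_table)
        assert table.n_sr_hr == 14
        assert table.n_hr_sr == 27
        assert not ids["unclassifiable"]

    def test_deterministic(self):
        a = build_study_replica()
        b = build_study_replica()
        assert [p.record for p in a] == [p.record for p in b]
        assert [p.protocols for p in a] == [p.protocols for p in b]


class TestGenerator:
    def test_seed_determinism_byte_identical(self, tmp_path):
        cfg = GeneratorConfig(n=300, seed=11)
        p1 = write_cohort_artifacts(generate_cohort(cfg), tmp_path / "a")
        p2 = write_cohort_artifacts(generate_cohort(cfg), tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_different_seeds_differ(self):
        a = generate_cohort(GeneratorConfig(n=200, seed=1))
        b = generate_cohort(GeneratorConfig(n=200, seed=2))
        assert [p.record for p in a] != [p.record for p in b]

    def test_zero_discordance_gives_perfect_agreement(self, protocol_table):
        cfg = GeneratorConfig(
            n=800, seed=5,
            discordance_rates={m: 0.0 for m in DISCORDANCE_MECHANISMS},
        )
        patients = generate_cohort(cfg)
        assert all(p.injected_discordance_reason is None for p in patients)
        table, _ = registry_vs_bio3(patients, protocol_table)
        assert table.n_hr_sr == 0 and table.n_sr_hr == 0

    def test_concordant_by_construction_without_injection(self, protocol_table):
        """Patients with no injected reason agree registry-vs-biology-3."""
        patients = generate_cohort(GeneratorConfig(n=1000, seed=9))
        analyzed, _ = apply_eligibility([p.record for p in patients])
        by_id = {p.record.patient_id: p for p in patients}
        reg = dict(
            classify_cohort_registry(
                analyzed, [pr for p in patients for pr in p.protocols], protocol_table
            )
        )
        for r in analyzed:
            p = by_id[r.patient_id]
            if p.injected_discordance_reason is None:
                assert reg[r.patient_id].label is p.true_biology[3]

    def test_parameter_recovery_large_n(self):
        """Category frequencies recover config probabilities (99% binomial)."""
        n = 5790
        cfg = GeneratorConfig(n=n, seed=123)
        patients = generate_cohort(cfg)

        def check(observed, p):
            half = 2.576 * math.sqrt(p * (1 - p) / n)
            assert abs(observed / n - p) <= half, (observed / n, p)

        check(
            sum(p.record.immunophenotype is Immunophenotype.T for p in patients),
            cfg.p_T,
        )
        for cyto, prob in cfg.cytogenetics_probs.items():
            check(
                sum(p.record.cytogenetics is cyto for p in patients), prob
            )
        fired = Counter(
            p.injected_discordance_reason
            for p in patients
            if p.injected_discordance_reason
        )
        for mech, rate in cfg.discordance_rates.items():
            check(fired[mech], rate)

    def test_age_distribution_median_and_iqr(self):
        patients = generate_cohort(GeneratorConfig(n=5790, seed=77))
        ages = np.array([p.record.age_years for p in patients])
        assert np.all(ages == np.floor(ages))  # integer years
        assert np.median(ages) == 4
        assert np.percentile(ages, 25) == 3
        assert np.percentile(ages, 75) == 8

    def test_mrd_positivity_enriched_in_hr_cytogenetics(self):
        patients = generate_cohort(GeneratorConfig(n=5790, seed=3))
        tested = [
            p.record for p in patients
            if p.record.mrd in (MRDStatus.POSITIVE, MRDStatus.NEGATIVE)
        ]
        hr = [r for r in tested if high_risk_cytogenetics(r.cytogenetics)]
        other = [r for r in tested if not high_risk_cytogenetics(r.cytogenetics)]
        rate_hr = sum(r.mrd is MRDStatus.POSITIVE for r in hr) / len(hr)
        rate_other = sum(r.mrd is MRDStatus.POSITIVE for r in other) / len(other)
        assert rate_hr > rate_other

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(GeneratorConfig(n=10, p_T=1.5))
        with pytest.raises(ValueError):
            generate_cohort(
                GeneratorConfig(n=10, cytogenetics_probs={Cytogenetics.MISSING: 0.5})
            )
        with pytest.raises(ValueError):
            generate_cohort(
                GeneratorConfig(n=10, discordance_rates={"bogus_mechanism": 0.1})
            )


class TestSummarize:
    def test_replica_summary_matches_contract_cells(self, replica_result):
        df = replica_result.summary.set_index("characteristic")
        assert df.loc["overall", "n"] == 579
        assert df.loc["overall", "alg1_sr"] == 359
        assert df.loc["overall", "alg3_hr"] == 239
        assert df.loc["immunophenotype_T", "n"] == 57
        assert df.loc["immunophenotype_T", "alg1_sr"] == 12
        assert df.loc["immunophenotype_T", "alg2_hr"] == 57
        assert df.loc["cytogenetics_high_risk", "n"] == 36
        assert df.loc["cytogenetics_high_risk", "alg3_hr"] == 36
        assert df.loc["mrd_positive", "n"] == 38
        assert df.loc["mrd_positive", "alg4_hr"] == 38

    def test_rows_partition_into_strata(self, replica_result):
        df = replica_result.summary
        for _, row in df.iterrows():
            for lv in (1, 2, 3, 4):
                assert row[f"alg{lv}_sr"] + row[f"alg{lv}_hr"] == row["n"]

    def test_empty_cohort_all_zero(self):
        df = summarize_cohort([], {1: {}})
        assert (df["n"] == 0).all()
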