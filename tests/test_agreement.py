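"""Agreement statistics: crosstab, Cohen's kappa, diagnostic metrics, bands."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riskproxy.agreement import (
    ContingencyTable2x2,
    KappaInterpretation,
    agreement_report,
    cohen_kappa,
    crosstab,
    diagnostic_metrics,
    interpret_kappa,
)
from riskproxy.cohort_model import RiskCall, RiskLabel, RiskSource

REPLICA_TABLE = ContingencyTable2x2(225, 27, 14, 313)


def calls(labels, source):
    return {f"P{i}": RiskCall(lab, source) for i, lab in enumerate(labels)}


def kappa_oracle(t: ContingencyTable2x2) -> float:
    """Independent kappa: expand the table into label pairs and recompute
    observed and chance agreement from the empirical marginals."""
    pairs = (
        [("HR", "HR")] * t.n_hr_hr
        + [("HR", "SR")] * t.n_hr_sr
        + [("SR", "HR")] * t.n_sr_hr
        + [("SR", "SR")] * t.n_sr_sr
    )
    n = len(pairs)
    po = sum(r == b for r, b in pairs) / n
    pe = sum(
        (sum(r == lab for r, _ in pairs) / n) * (sum(b == lab for _, b in pairs) / n)
        for lab in ("SR", "HR")
    )
    return (po - pe) / (1 - pe)


class TestCrosstab:
    def test_replica_reconstruction(self, replica_result):
        t = replica_result.report["levels"][3].table
        assert (t.n_hr_hr, t.n_hr_sr, t.n_sr_hr, t.n_sr_sr) == (225, 27, 14, 313)

    def test_identical_calls_no_discordance(self):
        reg = calls([RiskLabel.SR, RiskLabel.HR, RiskLabel.SR], RiskSource.REGISTRY)
        bio = calls([RiskLabel.SR, RiskLabel.HR, RiskLabel.SR], RiskSource.BIOLOGY_3)
        t, ids = crosstab(reg, bio)
        assert t.n_hr_sr == t.n_sr_hr == 0
        assert ids["hr_sr"] == ids["sr_hr"] == []

    def test_disjoint_patient_sets_rejected(self):
        reg = calls([RiskLabel.SR], RiskSource.REGISTRY)
        bio = {"Q1": RiskCall(RiskLabel.SR, RiskSource.BIOLOGY_3)}
        with pytest.raises(ValueError, match="mismatched"):
            crosstab(reg, bio)

    def test_unclassifiable_excluded_and_reported(self):
        reg = {
            "P0": RiskCall(RiskLabel.UNCLASSIFIABLE, RiskSource.REGISTRY),
            "P1": RiskCall(RiskLabel.SR, RiskSource.REGISTRY),
        }
        bio = {
            "P0": RiskCall(RiskLabel.SR, RiskSource.BIOLOGY_3),
            "P1": RiskCall(RiskLabel.SR, RiskSource.BIOLOGY_3),
        }
        t, ids = crosstab(reg, bio)
        assert t.n == 1
        assert ids["unclassifiable"] == ["P0"]

    def test_discordant_ids_reported_by_cell(self):
        reg = calls([RiskLabel.HR, RiskLabel.SR], RiskSource.REGISTRY)
        bio = calls([RiskLabel.SR, RiskLabel.HR], RiskSource.BIOLOGY_3)
        _, ids = crosstab(reg, bio)
        assert ids["hr_sr"] == ["P0"] and ids["sr_hr"] == ["P1"]


class TestCohenKappa:
    def test_reconstructed_table_values(self):
        kappa, se, lo, hi = cohen_kappa(REPLICA_TABLE)
        assert kappa == pytest.approx(0.8551, abs=5e-4)
        assert lo == pytest.approx(0.812, abs=1e-3)
        assert hi == pytest.approx(0.898, abs=1e-3)

    def test_perfect_agreement(self):
        kappa, _, _, _ = cohen_kappa(ContingencyTable2x2(7, 0, 0, 5))
        assert kappa == pytest.approx(1.0)

    def test_chance_agreement_zero(self):
        kappa, _, _, _ = cohen_kappa(ContingencyTable2x2(25, 25, 25, 25))
        assert kappa == pytest.approx(0.0)

    def test_degenerate_marginals_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            cohen_kappa(ContingencyTable2x2(10, 0, 0, 0))
        with pytest.raises(ValueError, match="empty"):
            cohen_kappa(ContingencyTable2x2(0, 0, 0, 0))

    def test_matches_oracle_on_all_small_tables(self):
        """Closed form equals brute-force po/pe on every table with n <= 12."""
        checked = 0
        for a, b, c, d in itertools.product(range(13), repeat=4):
            if not 0 < a + b + c + d <= 12:
                continue
            t = ContingencyTable2x2(a, b, c, d)
            n = t.n
            pe = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
            if pe >= 1.0:
                continue
            kappa, _, _, _ = cohen_kappa(t)
            assert kappa == pytest.approx(kappa_oracle(t), abs=1e-12)
            checked += 1
        assert checked > 1000

    def test_matches_sklearn_on_random_tables(self):
        """Cross-check against an independent library implementation."""
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(0)
        for _ in range(25):
            a, b, c, d = rng.integers(1, 60, size=4)
            t = ContingencyTable2x2(int(a), int(b), int(c), int(d))
            reg = ["HR"] * (a + b) + ["SR"] * (c + d)
            bio = ["HR"] * a + ["SR"] * b + ["HR"] * c + ["SR"] * d
            expected = sklearn_metrics.cohen_kappa_score(reg, bio)
            kappa, _, _, _ = cohen_kappa(t)
            assert kappa == pytest.approx(expected, abs=1e-12)

    def test_transposition_invariance(self):
        kappa, _, _, _ = cohen_kappa(REPLICA_TABLE)
        kappa_t, _, _, _ = cohen_kappa(REPLICA_TABLE.transpose())
        assert kappa == pytest.approx(kappa_t, abs=1e-12)

    def test_ci_shrinks_with_sample_size(self):
        k1, se1, _, _ = cohen_kappa(REPLICA_TABLE)
        k4, se4, _, _ = cohen_kappa(REPLICA_TABLE.scaled(4))
        assert k4 == pytest.approx(k1, abs=1e-12)  # kappa unchanged
        assert se4 == pytest.approx(se1 / 2, rel=1e-9)  # SE ~ 1/sqrt(n)

    def test_fleiss_se_option(self):
        _, se_simple, _, _ = cohen_kappa(REPLICA_TABLE, se_method="simple")
        _, se_fleiss, _, _ = cohen_kappa(REPLICA_TABLE, se_method="fleiss")
        assert se_fleiss > 0
        assert se_fleiss != se_simple

    @given(
        a=st.integers(0, 40), b=st.integers(0, 40),
        c=st.integers(0, 40), d=st.integers(0, 40),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_kappa_bounded_and_ci_brackets(self, a, b, c, d):
        t = ContingencyTable2x2(a, b, c, d)
        n = t.n
        if n == 0:
            return
        pe = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
        if pe >= 1.0:
            return
        kappa, se, lo, hi = cohen_kappa(t)
        assert -1.0 - 1e-12 <= kappa <= 1.0 + 1e-12
        assert lo <= kappa <= hi
        assert se >= 0
        # kappa = 1 iff the off-diagonals vanish
        assert (math.isclose(kappa, 1.0)) == (b == 0 and c == 0)


class TestDiagnosticMetrics:
    def test_reconstructed_table(self):
        sens, spec, ppv, npv = diagnostic_metrics(REPLICA_TABLE)
        assert sens == pytest.approx(225 / 239, abs=1e-12)
        assert spec == pytest.approx(313 / 340, abs=1e-12)
        assert ppv == pytest.approx(225 / 252, abs=1e-12)
        assert npv == pytest.approx(313 / 327, abs=1e-12)

    def test_perfect_table(self):
        assert diagnostic_metrics(ContingencyTable2x2(10, 0, 0, 10)) == (
            1.0, 1.0, 1.0, 1.0,
        )

    def test_zero_denominator_returns_missing(self):
        sens, spec, ppv, npv = diagnostic_metrics(ContingencyTable2x2(0, 5, 0, 5))
        assert sens is None  # no biology-HR patients
        assert spec is not None

    def test_transposition_swaps_sens_ppv_and_spec_npv(self):
        sens, spec, ppv, npv = diagnostic_metrics(REPLICA_TABLE)
        sens_t, spec_t, ppv_t, npv_t = diagnostic_metrics(REPLICA_TABLE.transpose())
        assert sens_t == pytest.approx(ppv) and ppv_t == pytest.approx(sens)
        assert spec_t == pytest.approx(npv) and npv_t == pytest.approx(spec)


class TestInterpretation:
    @pytest.mark.parametrize(
        "k,band",
        [
            (0.85, KappaInterpretation.ALMOST_PERFECT),
            (0.81, KappaInterpretation.ALMOST_PERFECT),
            (0.80, KappaInterpretation.SUBSTANTIAL),
            (0.61, KappaInterpretation.SUBSTANTIAL),
            (0.60, KappaInterpretation.MODERATE),
            (0.41, KappaInterpretation.MODERATE),
            (0.40, KappaInterpretation.FAIR),
            (0.205, KappaInterpretation.FAIR),  # gap assigned upward
            (0.20, KappaInterpretation.SLIGHT),
            (0.0, KappaInterpretation.SLIGHT),
            (-0.3, KappaInterpretation.SLIGHT),  # worse than chance
        ],
    )
    def test_landis_koch_bands(self, k, band):
        assert interpret_kappa(k) is band

    def test_kappa_above_one_rejected(self):
        with pytest.raises(ValueError):
            interpret_kappa(1.1)


class TestAgreementReport:
    def test_replica_level_3_row(self, replica_result):
        res = replica_result.report["levels"][3]
        assert round(res.kappa, 2) in (0.85, 0.86)
        assert round(res.ci_low, 2) == 0.81
        assert round(res.ci_high, 2) == 0.90
        assert round(res.sensitivity, 2) == 0.94
        assert round(res.ppv, 2) == 0.89
        assert round(res.npv, 2) == 0.96
        assert res.interpretation is KappaInterpretation.ALMOST_PERFECT

    def test_all_levels_reported(self, replica_result):
        assert set(replica_result.report["levels"]) == {1, 2, 3, 4}

    def test_discordant_listing_carries_reasons(self, replica_result):
        listing = replica_result.report["discordant"][3]
        assert len(listing) == 41
        reasons = [e.get("reason") for e in listing]
        assert reasons.count("data_entry_error") == 9
        assert reasons.count("knowledge_drift") == 12
        assert reasons.count("unmeasured_risk_factor") == 12
        assert reasons.count("clinician_override") == 8

    def test_single_patient_degenerate_levels_surface_errors(self):
        reg = {"P0": RiskCall(RiskLabel.SR, RiskSource.REGISTRY)}
        bio = {1: {"P0": RiskCall(RiskLabel.SR, RiskSource.BIOLOGY_1)}}
        report = agreement_report(reg, bio)
        assert "error" in report["levels"][1]
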