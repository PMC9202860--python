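from datetime import datetime, timedelta

import numpy as np
import pytest
from scipy import special

from bilinorm.adherence_audit import (
    AuditResult,
    Classification,
    ContingencyTable,
    Epoch,
    TreatmentRecord,
    classify_treatment,
    compare_epochs,
    pearson_chi_square,
    summarize_epochs,
)
from bilinorm.decision_engine import PatientRecord, RiskFactor, TSBUnit
from bilinorm.guideline_tables import Intervention, RiskClass, stratum_for

B = datetime(2019, 3, 1)


def _record(tsb, pt_given, epoch=Epoch.PRE, age_h=48.0, ga=33, bw=2100,
            risk=frozenset({RiskFactor.UNKNOWN})):
    patient = PatientRecord(
        ga_weeks=ga,
        birth_datetime=B,
        record_datetime=B + timedelta(hours=age_h),
        bw_g=bw,
        tsb_value=tsb,
        tsb_unit=TSBUnit.MG_DL,
        risk_factors=risk,
    )
    return TreatmentRecord(
        patient=patient,
        tsb_measured=tsb is not None,
        pt_given=pt_given,
        exchange_given=False,
        epoch=epoch,
    )


def _pt_threshold(guideline, ga=33, bw=2100, age_h=48.0, rc=RiskClass.WITH_RISK):
    return guideline.threshold(
        stratum_for(ga, bw), Intervention.PHOTOTHERAPY, rc, age_h
    )


class TestClassifyTreatment:
    def test_above_threshold_untreated_is_under_treatment(self, guideline):
        thr = _pt_threshold(guideline)
        res = classify_treatment(_record(thr + 2.0, pt_given=False), guideline)
        assert res.classification is Classification.UNDER_TREATMENT

    def test_below_threshold_treated_is_over_treatment(self, guideline):
        thr = _pt_threshold(guideline)
        res = classify_treatment(_record(thr - 2.0, pt_given=True), guideline)
        assert res.classification is Classification.OVER_TREATMENT

    def test_phototherapy_without_tsb_is_inappropriate(self, guideline):
        res = classify_treatment(_record(None, pt_given=True), guideline)
        assert res.classification is Classification.INAPPROPRIATE
        assert res.indicated is None

    def test_no_tsb_no_treatment_is_unevaluable(self, guideline):
        res = classify_treatment(_record(None, pt_given=False), guideline)
        assert res.classification is Classification.UNEVALUABLE

    def test_agreement_both_ways_is_correct(self, guideline):
        thr = _pt_threshold(guideline)
        assert (
            classify_treatment(_record(thr + 2.0, pt_given=True), guideline)
            .classification
            is Classification.CORRECT
        )
        assert (
            classify_treatment(_record(thr - 2.0, pt_given=False), guideline)
            .classification
            is Classification.CORRECT
        )

    def test_exhaustive_and_mutually_exclusive_over_lattice(self, guideline):
        """Every (tsb presence, threshold side, pt flag) cell maps to exactly
        one classification, and the map covers all five outcomes."""
        thr = _pt_threshold(guideline)
        seen = set()
        for tsb in (None, thr - 1.0, thr, thr + 1.0):
            for pt_given in (False, True):
                res = classify_treatment(_record(tsb, pt_given=pt_given), guideline)
                assert isinstance(res.classification, Classification)
                seen.add(res.classification)
        assert seen == set(Classification)

    def test_record_tsb_consistency_enforced(self):
        with pytest.raises(ValueError):
            TreatmentRecord(
                patient=_record(5.0, pt_given=False).patient,
                tsb_measured=False,
                pt_given=False,
                exchange_given=False,
                epoch=Epoch.PRE,
            )


class TestSummarizeEpochs:
    def test_single_correct_record_per_epoch(self, guideline):
        thr = _pt_threshold(guideline)
        results = [
            classify_treatment(_record(thr + 1, True, Epoch.PRE), guideline),
            classify_treatment(_record(thr - 1, False, Epoch.POST), guideline),
        ]
        table = summarize_epochs(results)
        assert table.counts == ((1, 1), (0, 0), (0, 0), (0, 0))

    def test_counts_partition_evaluable_records(self, guideline):
        thr = _pt_threshold(guideline)
        results = [
            classify_treatment(_record(tsb, pt, epoch), guideline)
            for epoch in Epoch
            for tsb, pt in [
                (thr + 1, True), (thr - 1, True), (thr + 1, False),
                (None, True), (None, False),
            ]
        ]
        table = summarize_epochs(results)
        n_evaluable = sum(
            1 for r in results if r.classification is not Classification.UNEVALUABLE
        )
        assert sum(sum(row) for row in table.counts) == n_evaluable

    def test_empty_epoch_rejected(self, guideline):
        thr = _pt_threshold(guideline)
        results = [classify_treatment(_record(thr + 1, True, Epoch.PRE), guideline)]
        with pytest.raises(ValueError, match="epoch"):
            summarize_epochs(results)


def _oracle_chi_square(obs):
    """Independent oracle: explicit O/E summation + regularized gamma sf."""
    obs = np.asarray(obs, dtype=float)
    total = obs.sum()
    stat = 0.0
    for i in range(obs.shape[0]):
        for j in range(obs.shape[1]):
            e = obs[i].sum() * obs[:, j].sum() / total
            stat += (obs[i, j] - e) ** 2 / e
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return stat, df, float(special.chdtrc(df, stat))


class TestPearsonChiSquare:
    @pytest.mark.parametrize(
        "counts,p3",
        [
            (((97, 93), (158, 88)), 0.006),
            (((36, 13), (219, 168)), 0.024),
        ],
    )
    def test_published_two_by_two_tables(self, counts, p3):
        res = pearson_chi_square(ContingencyTable(("a", "b"), counts))
        assert round(res.p_value, 3) == p3

    def test_identical_column_proportions_give_null(self):
        res = pearson_chi_square(
            ContingencyTable(("a", "b"), ((30, 15), (50, 25)))
        )
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_oracle_on_random_tables(self):
        """Agreement with the explicit O/E + gamma-sf oracle to 1e-10."""
        rng = np.random.default_rng(17)
        for _ in range(1000):
            r = int(rng.integers(2, 6))
            obs = rng.integers(1, 200, size=(r, 2))
            table = ContingencyTable(
                tuple(f"r{i}" for i in range(r)),
                tuple(tuple(int(c) for c in row) for row in obs),
            )
            res = pearson_chi_square(table)
            stat, df, p = _oracle_chi_square(obs)
            assert res.statistic == pytest.approx(stat, abs=1e-10)
            assert res.df == df
            assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_column_swap_invariance(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            obs = rng.integers(1, 100, size=(4, 2))
            t1 = ContingencyTable(("a", "b", "c", "d"),
                                  tuple(tuple(int(c) for c in row) for row in obs))
            t2 = ContingencyTable(("a", "b", "c", "d"),
                                  tuple((int(row[1]), int(row[0])) for row in obs))
            r1, r2 = pearson_chi_square(t1), pearson_chi_square(t2)
            assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)
            assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            pearson_chi_square(ContingencyTable(("a", "b"), ((0, 0), (5, 3))))


class TestCompareEpochs:
    def test_identical_epochs_give_unit_p_values(self, guideline):
        thr = _pt_threshold(guideline)
        results = []
        for epoch in Epoch:
            results += [
                classify_treatment(_record(thr + 1, True, epoch), guideline),
                classify_treatment(_record(thr - 1, True, epoch), guideline),
                classify_treatment(_record(thr + 1, False, epoch), guideline),
                classify_treatment(_record(None, True, epoch), guideline),
            ]
        rep = compare_epochs(results)
        assert rep.overall.p_value == pytest.approx(1.0)
        for res in rep.per_category.values():
            assert res.p_value == pytest.approx(1.0)

    def test_demographic_tables_derived_from_records(self, guideline):
        thr = _pt_threshold(guideline)
        results = []
        for epoch in Epoch:
            results += [
                classify_treatment(
                    _record(thr + 1, True, epoch, ga=33, bw=2100), guideline
                ),
                classify_treatment(
                    _record(12.0, True, epoch, ga=38, bw=3200,
                            risk=frozenset({RiskFactor.NONE_DECLARED})),
                    guideline,
                ),
            ]
        rep = compare_epochs(results)
        assert set(rep.demographics) == {"ga", "bw", "risk"}
        ga_table, _ = rep.demographics["ga"]
        assert ga_table.counts == ((1, 1), (1, 1))

    def test_unevaluable_counted_separately(self, guideline):
        thr = _pt_threshold(guideline)
        results = [
            classify_treatment(_record(thr + 1, True, e), guideline) for e in Epoch
        ] + [classify_treatment(_record(None, False, Epoch.PRE), guideline)]
        rep = compare_epochs(results)
        assert rep.n_unevaluable == 1
        assert sum(sum(r) for r in rep.classification_table.counts) == 2
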