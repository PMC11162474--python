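"""Threshold calibration, contingency analysis, correlation and referral."""

import itertools
import math

import numpy as np
import pytest

from uqseg import (
    CohortRecord,
    Contingency,
    UncertaintyThreshold,
    batch_referral,
    calibrate_threshold,
    certainty_correlation,
    classify,
    conditional_probs,
    evaluate_cohort,
    instance_referral,
    referral_auc,
)
from uqseg.evaluation import frame_to_records, records_to_frame


def rec(pid, u, d, split="evaluation", msd=1.0, hd=2.0, flags=()):
    return CohortRecord(
        patient_id=pid, uncertainty={"cv": u}, dsc=d, msd=msd, hd95=hd,
        split=split, flags=flags,
    )


def cohort_from(pairs, **kw):
    return [rec(f"P{i:02d}", u, d, **kw) for i, (u, d) in enumerate(pairs)]


class TestCalibration:
    def test_two_point_exact_line(self):
        records = cohort_from([(1.0, 0.5), (0.0, 1.0)])
        th = calibrate_threshold(records, "cv", dsc_target=0.61)
        assert th.slope == pytest.approx(-2.0)
        assert th.intercept == pytest.approx(2.0)
        assert th.tau == pytest.approx(0.78)

    def test_flat_uncertainty_gives_constant_tau(self):
        records = cohort_from([(0.3, 0.2), (0.3, 0.6), (0.3, 0.9)])
        for target in (0.1, 0.61, 0.95):
            assert calibrate_threshold(records, "cv", target).tau == pytest.approx(0.3)

    def test_default_anchor_is_interobserver_dsc(self):
        records = cohort_from([(1.0, 0.5), (0.0, 1.0)])
        assert calibrate_threshold(records, "cv").dsc_anchor == 0.61

    def test_identical_dsc_raises(self):
        records = cohort_from([(0.1, 0.5), (0.9, 0.5)])
        with pytest.raises(ValueError):
            calibrate_threshold(records, "cv")

    def test_affine_equivariance(self, rng):
        pairs = [(float(u), float(d)) for u, d in rng.random((10, 2))]
        records = cohort_from(pairs)
        scaled = cohort_from([(3.0 * u + 5.0, d) for u, d in pairs])
        t1 = calibrate_threshold(records, "cv", 0.7).tau
        t2 = calibrate_threshold(scaled, "cv", 0.7).tau
        assert t2 == pytest.approx(3.0 * t1 + 5.0)


class TestClassifyAndConditionals:
    def test_all_certain_accurate(self):
        th = UncertaintyThreshold("cv", tau=1.0, dsc_anchor=0.61, slope=0, intercept=1)
        records = cohort_from([(0.5, 0.9)] * 4)
        c = classify(records, th)
        assert (c.n_ac, c.n_au, c.n_ic, c.n_iu) == (4, 0, 0, 0)

    def test_tau_tie_is_certain(self):
        th = UncertaintyThreshold("cv", tau=0.5, dsc_anchor=0.61, slope=0, intercept=0)
        c = classify([rec("a", 0.5, 0.9)], th)
        assert c.n_ac == 1

    def test_degenerate_is_uncertain(self):
        th = UncertaintyThreshold("cv", tau=10.0, dsc_anchor=0.61, slope=0, intercept=0)
        c = classify([rec("a", float("nan"), 0.9)], th)
        assert c.n_au == 1

    def test_hand_counted_cells(self):
        # constructed placements: tau = 0.5, dsc_cut = 0.61
        th = UncertaintyThreshold("cv", tau=0.5, dsc_anchor=0.61, slope=0, intercept=0)
        pairs = (
            [(0.1, 0.9)] * 5      # certain, accurate
            + [(0.2, 0.3)]        # certain, inaccurate
            + [(0.9, 0.8)]        # uncertain, accurate
            + [(0.8, 0.2)] * 3    # uncertain, inaccurate
        )
        c = classify(cohort_from(pairs), th)
        assert (c.n_ac, c.n_ic, c.n_au, c.n_iu) == (5, 1, 1, 3)
        p_ac, p_iu, au = conditional_probs(c)
        assert p_ac == pytest.approx(5 / 6)
        assert p_iu == pytest.approx(3 / 4)
        assert au == pytest.approx(0.8)

    def test_counts_sum_to_n_and_au_identity(self, rng):
        th = UncertaintyThreshold("cv", tau=0.5, dsc_anchor=0.61, slope=0, intercept=0)
        records = cohort_from([(float(u), float(d)) for u, d in rng.random((30, 2))])
        c = classify(records, th)
        assert c.n == 30
        _, _, au = conditional_probs(c)
        assert au == pytest.approx((c.n_ac + c.n_iu) / 30)

    def test_zero_denominators_flagged_absent(self):
        p_ac, p_iu, au = conditional_probs(Contingency(0, 2, 0, 3))
        assert p_ac is None and p_iu == pytest.approx(0.6)
        p_ac, p_iu, au = conditional_probs(Contingency(4, 0, 1, 0))
        assert p_iu is None
        assert conditional_probs(Contingency(2, 2, 2, 2))[2] == pytest.approx(0.5)


class TestCorrelation:
    def test_perfect_linear(self):
        records = cohort_from([(-d, d) for d in (0.2, 0.5, 0.8, 0.9)])
        rho, p = certainty_correlation(records, "cv")
        assert rho == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        records = cohort_from([(d, d) for d in (0.2, 0.5, 0.8, 0.9)])
        rho, _ = certainty_correlation(records, "cv")
        assert rho == pytest.approx(-1.0)

    def test_matches_direct_pearson_formula(self):
        pairs = [(0.9, 0.2), (0.4, 0.5), (0.7, 0.3), (0.1, 0.95), (0.5, 0.6)]
        records = cohort_from(pairs)
        rho, _ = certainty_correlation(records, "cv")
        d = np.array([p[1] for p in pairs])
        c = -np.array([p[0] for p in pairs])
        manual = ((d - d.mean()) * (c - c.mean())).sum() / math.sqrt(
            ((d - d.mean()) ** 2).sum() * ((c - c.mean()) ** 2).sum()
        )
        assert rho == pytest.approx(manual, abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            certainty_correlation(cohort_from([(0.5, 0.5)] * 5), "cv")


class TestBatchReferral:
    def test_two_patient_curve(self):
        records = cohort_from([(0.9, 0.2), (0.1, 0.8)])
        curve = batch_referral(records, "cv", stop_fraction=0.10)
        assert curve.points == ((0, pytest.approx(0.5)), (1, pytest.approx(0.8)))

    def test_oracle_ranking_nondecreasing(self, rng):
        dscs = rng.random(20)
        records = cohort_from([(-d, d) for d in dscs])
        curve = batch_referral(records, "cv")
        assert (np.diff(curve.retained_means) >= -1e-12).all()

    def test_anti_oracle_nonincreasing(self, rng):
        dscs = rng.random(20)
        records = cohort_from([(d, d) for d in dscs])
        curve = batch_referral(records, "cv")
        assert (np.diff(curve.retained_means) <= 1e-12).all()

    def test_stop_rule_retains_ceil_fraction(self):
        for n in (2, 7, 10, 20, 67):
            records = cohort_from([(i / n, 0.5 + 0.4 * i / n) for i in range(n)])
            curve = batch_referral(records, "cv", stop_fraction=0.10)
            n_removed_max = curve.points[-1][0]
            assert n - n_removed_max == math.ceil(0.10 * n)

    def test_degenerate_sorts_most_uncertain(self):
        records = cohort_from([(0.1, 0.9), (0.2, 0.8)])
        records.append(rec("Pzz", float("nan"), 0.1))
        curve = batch_referral(records, "cv")
        # first removal drops the degenerate patient
        assert curve.points[1][1] == pytest.approx(0.85)

    def test_auc_conventions(self):
        c = batch_referral(cohort_from([(0.9, 0.7), (0.1, 0.7)]), "cv")
        assert referral_auc(c) == pytest.approx(0.7)
        c2 = batch_referral(cohort_from([(0.9, 0.2), (0.1, 0.8)]), "cv")
        assert referral_auc(c2) == pytest.approx(0.65)

    def test_oracle_maximizes_auc_exhaustively(self, rng):
        # over all permutations of a small cohort, ranking by -DSC achieves
        # the maximal area under the referral curve
        dscs = [0.15, 0.3, 0.55, 0.7, 0.85, 0.95]
        oracle = cohort_from([(-d, d) for d in dscs])
        best = referral_auc(batch_referral(oracle, "cv"))
        for perm in itertools.permutations(range(len(dscs))):
            records = [
                rec(f"P{i:02d}", float(rank), dscs[i])
                for rank, i in enumerate(perm)
            ]
            auc = referral_auc(batch_referral(records, "cv"))
            assert auc <= best + 1e-12

    def test_oracle_auc_at_least_cohort_mean(self, rng):
        for _ in range(10):
            dscs = rng.random(15)
            records = cohort_from([(-d, d) for d in dscs])
            auc = referral_auc(batch_referral(records, "cv"))
            assert auc >= dscs.mean() - 1e-12


class TestInstanceReferral:
    def _th(self, tau):
        return UncertaintyThreshold("cv", tau=tau, dsc_anchor=0.8, slope=0, intercept=0)

    def test_tau_below_everyone(self):
        ids, mean, n = instance_referral(cohort_from([(0.5, 0.9)] * 3), self._th(0.1))
        assert (ids, mean, n) == ([], None, 0)

    def test_tau_above_everyone_full_cohort_mean(self, rng):
        pairs = [(float(u), float(d)) for u, d in rng.random((12, 2))]
        ids, mean, n = instance_referral(cohort_from(pairs), self._th(math.inf))
        assert n == 12
        assert mean == pytest.approx(np.mean([d for _, d in pairs]))

    def test_exact_selection(self):
        pairs = [(0.1, 0.9), (0.2, 0.8), (0.3, 0.7)] + [(0.9, 0.2)] * 7
        ids, mean, n = instance_referral(cohort_from(pairs), self._th(0.5))
        assert n == 3
        assert mean == pytest.approx((0.9 + 0.8 + 0.7) / 3)

    def test_degenerate_always_referred(self):
        records = [rec("a", float("nan"), 0.9), rec("b", 0.1, 0.8)]
        ids, mean, n = instance_referral(records, self._th(10.0))
        assert ids == ["b"] and n == 1


class TestCohortReportAndCSV:
    def _full_records(self, rng, n=16):
        records = []
        for i in range(n):
            d = float(rng.uniform(0.2, 0.95))
            u = {m: 1.0 - d + float(rng.normal(0, 0.05)) for m in
                 ("h", "eh", "mi", "cv", "seh", "sh", "si")}
            u["r_dsc"] = -d + float(rng.normal(0, 0.05))
            records.append(
                CohortRecord(
                    patient_id=f"P{i:03d}", uncertainty=u, dsc=d,
                    msd=float(rng.uniform(0.5, 4)), hd95=float(rng.uniform(1, 9)),
                    split="calibration" if i < n // 2 else "evaluation",
                )
            )
        return records

    def test_csv_round_trip(self, rng):
        records = self._full_records(rng)
        back = frame_to_records(records_to_frame(records))
        assert [r.patient_id for r in back] == [r.patient_id for r in records]
        for a, b in zip(records, back):
            assert a.uncertainty == pytest.approx(b.uncertainty)
            assert a.split == b.split and a.dsc == pytest.approx(b.dsc)

    def test_report_structure(self, rng):
        report = evaluate_cohort(self._full_records(rng))
        assert set(report["measures"]) == {
            "h", "eh", "mi", "cv", "seh", "sh", "si", "r_dsc"
        }
        cv = report["measures"]["cv"]
        assert 0 <= cv["au"] <= 1
        assert {"dsc", "msd", "hd95"} <= set(cv["referral"])
        assert set(cv["instance_referral"]) == {"tau_0.80", "tau_0.85", "tau_0.90"}

    def test_missing_split_raises(self, rng):
        records = self._full_records(rng)
        for r in records:
            r.split = "evaluation"
        with pytest.raises(ValueError):
            evaluate_cohort(records)
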