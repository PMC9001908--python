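"""Dice / MAE / acceptable rate, stratified reporting and group comparisons."""

from __future__ import annotations

import numpy as np
import pytest

from endoseg.datatypes import BinaryMask, ConfusionCounts, EvaluationRecord
from endoseg.evaluation import (
    acceptable_rate,
    confusion_counts,
    dice,
    dice_masks,
    mae,
    null_simulation,
    pathology_comparison,
    records_from_stratum_counts,
    report_to_frame,
    stratified_report,
)
from endoseg.exceptions import DegenerateTestError, ValidationError

from conftest import random_blob_mask


def rec(pred, ref, pathology=None, case_id="c"):
    return EvaluationRecord(
        case_id=case_id, predicted_mm=pred, reference_mm=ref, pathology=pathology
    )


class TestConfusionAndDice:
    def test_hand_tally_on_3x3(self):
        pred = np.zeros((3, 3), dtype=bool)
        pred[[0, 1], 0] = True
        truth = np.zeros((3, 3), dtype=bool)
        truth[:, 0] = True
        c = confusion_counts(BinaryMask(pred), BinaryMask(truth))
        assert (c.TP, c.FN, c.FP, c.TN) == (2, 1, 0, 6)
        assert c.total == 9

    def test_identical_masks_score_one(self):
        m = BinaryMask(np.eye(5, dtype=bool))
        assert dice_masks(m, m) == 1.0

    def test_disjoint_masks_score_zero(self):
        a = np.zeros((4, 4), dtype=bool)
        a[0] = True
        b = np.zeros((4, 4), dtype=bool)
        b[2] = True
        assert dice_masks(BinaryMask(a), BinaryMask(b)) == 0.0

    def test_direct_evaluation(self):
        assert dice(ConfusionCounts(TP=2, FP=1, FN=1, TN=0)) == pytest.approx(
            0.6667, abs=1e-4
        )

    def test_both_empty_convention(self):
        assert dice(ConfusionCounts(TP=0, FP=0, FN=0, TN=9)) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            confusion_counts(
                BinaryMask(np.zeros((2, 2), dtype=bool)),
                BinaryMask(np.zeros((3, 3), dtype=bool)),
            )

    def test_symmetry_and_setwise_equivalence(self, rng):
        for _ in range(20):
            a = random_blob_mask(rng, max_side=20)
            b = random_blob_mask(rng, max_side=20)
            h = max(a.shape[0], b.shape[0])
            w = max(a.shape[1], b.shape[1])
            aa = np.zeros((h, w), dtype=bool)
            aa[: a.shape[0], : a.shape[1]] = a
            bb = np.zeros((h, w), dtype=bool)
            bb[: b.shape[0], : b.shape[1]] = b
            d = dice_masks(BinaryMask(aa), BinaryMask(bb))
            assert d == dice_masks(BinaryMask(bb), BinaryMask(aa))
            setwise = 2.0 * (aa & bb).sum() / (aa.sum() + bb.sum())
            assert d == pytest.approx(setwise)


class TestMaeAndAcceptableRate:
    def test_hand_values(self):
        records = [rec(3.0, 2.0), rec(1.0, 3.0), rec(9.0, 6.0)]  # errors 1, 2, 3
        assert mae(records) == pytest.approx(2.0)

    def test_perfect_agreement_is_zero(self):
        assert mae([rec(4.2, 4.2), rec(7.0, 7.0)]) == 0.0

    def test_signed_pairs(self):
        records = [rec(4.0, 2.0), rec(2.5, 3.5)]
        assert mae(records) == pytest.approx(1.5)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            mae([])
        with pytest.raises(ValidationError):
            acceptable_rate([])

    def test_rate_fraction(self):
        records = [rec(2.0 + e, 2.0) for e in [0.5] * 191 + [5.0] * 23]
        assert acceptable_rate(records, threshold_mm=3.0, strict=False) == pytest.approx(
            100.0 * 191 / 214
        )
        assert round(acceptable_rate(records, threshold_mm=3.0, strict=False), 1) == 89.3

    def test_all_within_is_100(self):
        assert acceptable_rate([rec(5.0, 5.5)] * 4, threshold_mm=2.0) == 100.0

    def test_strictness_at_the_boundary(self):
        records = [rec(5.0, 3.0)]  # error exactly 2.0
        assert acceptable_rate(records, threshold_mm=2.0, strict=True) == 0.0
        assert acceptable_rate(records, threshold_mm=2.0, strict=False) == 100.0

    def test_monotone_in_threshold(self, rng):
        records = [rec(float(p), float(r)) for p, r in rng.uniform(0, 20, size=(30, 2))]
        rates = [
            acceptable_rate(records, threshold_mm=t) for t in (0.5, 1, 2, 3, 5, 10, 25)
        ]
        assert all(a <= b for a, b in zip(rates, rates[1:]))


class TestStratifiedReport:
    def test_published_count_pattern(self):
        records = records_from_stratum_counts([(22, 12), (130, 124), (62, 61)])
        report = stratified_report(records)
        rates = [round(r.acceptable_rate_percent, 1) for r in report.strata]
        assert rates == [54.5, 95.4, 98.4]
        assert report.total.n_cases == 214
        assert report.total.n_within == 12 + 124 + 61

    def test_totals_conserved(self, rng):
        records = [rec(float(p), float(r)) for p, r in rng.uniform(0, 20, size=(50, 2))]
        report = stratified_report(records)
        assert sum(r.n_cases for r in report.strata) == report.total.n_cases
        for row in report.rows:
            assert row.n_within + row.n_over == row.n_cases

    def test_reference_exactly_on_lower_bound(self):
        report = stratified_report([rec(4.0, 3.0)])
        assert report.strata[0].n_cases == 1
        assert report.strata[1].n_cases == 0

    def test_empty_stratum_rendered_as_dash(self):
        report = stratified_report([rec(6.0, 6.5)] * 3)
        frame = report_to_frame(report)
        assert (frame["acceptable_rate_percent"] == "—").sum() == 2
        assert report.strata[0].acceptable_rate_percent is None


class TestPathologyComparison:
    def test_identical_groups_give_t_zero_p_one(self):
        records = [rec(1.0 + e, 1.0, "N", f"n{i}") for i, e in enumerate([1, 2, 3])]
        records += [rec(1.0 + e, 1.0, "P", f"p{i}") for i, e in enumerate([1, 2, 3])]
        result = pathology_comparison(records)
        row = result.pairs.iloc[0]
        assert row["t"] == pytest.approx(0.0)
        assert row["p_two_tail"] == pytest.approx(1.0)

    def test_welch_example(self):
        records = [rec(2.0 + e, 2.0, "N", f"n{i}") for i, e in enumerate([1, 2, 3, 4, 5])]
        records += [rec(2.0 + e, 2.0, "P", f"p{i}") for i, e in enumerate([2, 3, 4, 5, 6])]
        result = pathology_comparison(records)
        row = result.pairs.iloc[0]
        assert row["t"] == pytest.approx(-1.0)
        assert row["df"] == pytest.approx(8.0)
        # p from the t distribution with 8 df at |t| = 1
        assert row["p_two_tail"] == pytest.approx(0.3466, abs=1e-3)
        assert row["p_one_tail"] == pytest.approx(0.1733, abs=1e-3)

    def test_bonferroni_is_three_times_min_p_capped(self, rng):
        records = []
        for label, loc in (("N", 0.0), ("P", 0.5), ("EC", -0.3)):
            for i, e in enumerate(rng.normal(loc, 1.0, size=12)):
                records.append(rec(max(0.0, 6.0 + e), 6.0, label, f"{label}{i}"))
        result = pathology_comparison(records)
        expected = min(1.0, 3.0 * result.pairs["p_two_tail"].min())
        assert result.bonferroni_two_tail == pytest.approx(expected)
        assert len(result.pairs) == 3

    def test_group_summaries_and_normality(self, rng):
        records = []
        for label in ("N", "P"):
            for i, e in enumerate(rng.normal(0, 1, size=10)):
                records.append(rec(max(0.0, 6.0 + e), 6.0, label, f"{label}{i}"))
        result = pathology_comparison(records)
        assert set(result.groups.index) == {"N", "P"}
        assert {"n", "mean", "variance", "shapiro_w", "shapiro_p"} <= set(
            result.groups.columns
        )
        assert (result.groups["shapiro_p"] > 0).all()

    def test_too_small_groups_rejected(self):
        records = [rec(1.0, 1.0, "N", "a"), rec(2.0, 1.0, "N", "b"), rec(1.5, 1.0, "P", "c")]
        with pytest.raises(ValidationError):
            pathology_comparison(records)
        with pytest.raises(ValidationError):
            pathology_comparison([rec(1.0, 1.0, "N", "a"), rec(2.0, 1.0, "N", "b")])

    def test_zero_variance_in_both_groups_is_degenerate(self):
        records = [rec(2.0, 1.0, "N", f"n{i}") for i in range(3)]
        records += [rec(3.0, 1.0, "P", f"p{i}") for i in range(3)]
        with pytest.raises(DegenerateTestError):
            pathology_comparison(records)


def test_null_simulation_keeps_corrected_p_high():
    coverage = null_simulation(n_replicates=30, group_sizes=(30, 15, 8), seed=5)
    assert coverage >= 90.0
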