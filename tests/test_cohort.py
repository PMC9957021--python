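"""Diagnostic statistics: T-score classes, ROC/Youden, performance."""

import numpy as np
import pandas as pd
import pytest

from tcmbmd import (
    accuracy_from_sens_spec,
    age_regression,
    classify_tscore,
    diagnostic_performance,
    pairwise_group_tests,
    pearson_r,
    roc_curve,
    youden_threshold,
)
from tcmbmd.cohort import round_half_away


def _mann_whitney_auc(scores, labels):
    """Pairwise concordance oracle: P(diseased scores below healthy), ties 1/2."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p < n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def _exhaustive_youden(scores, labels):
    roc = roc_curve(scores, labels)
    best = None
    for t, se, sp in zip(roc.thresholds, roc.sensitivity, roc.specificity):
        j = se + sp - 1.0
        key = (round(j, 12), round(se, 12), -t)
        if best is None or key > best[0]:
            best = (key, (t, se, sp))
    return best[1]


class TestClassification:
    @pytest.mark.parametrize(
        "tscores, expected",
        [
            ((-0.2, 0.1, 0.4, 0.3), "normal"),
            ((-1.0, 0, 0, 0), "osteopenia"),  # -1 is inside the osteopenia band
            ((-2.5, 0, 0, 0), "osteoporosis"),  # boundary included
            ((-0.99,), "normal"),
            ((-2.49, 1.0), "osteopenia"),
        ],
    )
    def test_lowest_tscore_rule(self, tscores, expected):
        assert classify_tscore(tscores) == expected

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            classify_tscore([])


class TestROC:
    def test_perfect_separation(self):
        roc = roc_curve([0.05, 0.08, 0.15, 0.20], [True, True, False, False])
        assert roc.auc == pytest.approx(1.0)
        thr, sens, spec = youden_threshold(roc)
        assert thr == pytest.approx((0.08 + 0.15) / 2)  # midpoint of the gap
        assert sens == 1.0 and spec == 1.0

    def test_all_ties_gives_half(self):
        roc = roc_curve([0.1] * 6, [True, True, True, False, False, False])
        assert roc.auc == pytest.approx(0.5)

    def test_six_point_mixed_set_matches_pair_enumeration(self):
        scores = [0.10, 0.12, 0.12, 0.15, 0.09, 0.20]
        labels = [True, True, False, False, True, False]
        assert roc_curve(scores, labels).auc == pytest.approx(
            _mann_whitney_auc(scores, labels)
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1.0, 2.0], [True, True])

    def test_auc_equals_concordance_on_random_instances(self, rng):
        for _ in range(60):
            n = int(rng.integers(4, 50))
            scores = np.round(rng.normal(0.12, 0.04, n), 3)  # rounding makes ties
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            assert roc_curve(scores, labels).auc == pytest.approx(
                _mann_whitney_auc(scores, labels)
            )

    def test_auc_cross_checked_against_sklearn(self, rng):
        sklearn = pytest.importorskip("sklearn.metrics")
        for _ in range(20):
            n = int(rng.integers(6, 40))
            scores = rng.normal(0.12, 0.05, n)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            # low score indicates disease, so sklearn sees negated scores
            assert roc_curve(scores, labels).auc == pytest.approx(
                sklearn.roc_auc_score(labels, -scores)
            )

    def test_monotone_sensitivity_specificity(self, rng):
        scores = rng.normal(0.1, 0.03, 30)
        labels = rng.random(30) < 0.4
        labels[0], labels[1] = True, False
        roc = roc_curve(scores, labels)
        assert np.all(np.diff(roc.sensitivity) >= 0)  # thresholds ascend
        assert np.all(np.diff(roc.specificity) <= 0)


class TestYouden:
    def test_matches_exhaustive_search_on_random_instances(self, rng):
        for _ in range(60):
            n = int(rng.integers(5, 50))
            scores = np.round(rng.normal(0.12, 0.04, n), 3)
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            assert youden_threshold(roc_curve(scores, labels)) == pytest.approx(
                _exhaustive_youden(scores, labels)
            )

    def test_returned_j_dominates_all_candidates(self, rng):
        scores = rng.normal(0.1, 0.05, 40)
        labels = rng.random(40) < 0.5
        labels[0], labels[1] = True, False
        roc = roc_curve(scores, labels)
        _, sens, spec = youden_threshold(roc)
        assert sens + spec - 1.0 >= np.max(roc.sensitivity + roc.specificity - 1.0) - 1e-12


class TestPerformance:
    def test_degenerate_thresholds(self):
        scores, labels = [0.1, 0.2, 0.3, 0.4], [True, True, False, False]
        low = diagnostic_performance(scores, labels, 0.05)
        assert (low.sensitivity, low.specificity) == (0.0, 100.0)
        high = diagnostic_performance(scores, labels, 0.5)
        assert (high.sensitivity, high.specificity) == (100.0, 0.0)

    def test_hand_counted_four_subject_set(self):
        # threshold 0.12: predictions (+,+,+,-); TP=2 FP=1 TN=1 FN=0
        perf = diagnostic_performance(
            [0.10, 0.12, 0.11, 0.15], [True, True, False, False], 0.12
        )
        assert perf.sensitivity == 100.0
        assert perf.specificity == 50.0
        assert perf.accuracy == 75.0

    def test_youden_point_reproduces_roc_entries(self, rng):
        scores = rng.normal(0.11, 0.04, 60)
        labels = rng.random(60) < 0.35
        labels[0], labels[1] = True, False
        roc = roc_curve(scores, labels)
        thr, sens, spec = youden_threshold(roc)
        perf = diagnostic_performance(scores, labels, thr)
        assert perf.sensitivity == pytest.approx(round_half_away(100 * sens))
        assert perf.specificity == pytest.approx(round_half_away(100 * spec))


class TestAccuracyReconstruction:
    @pytest.mark.parametrize(
        "sens, spec, n_pos, n_neg, expected",
        [
            (100.0, 100.0, 10, 20, 100.0),
            # published experimental-cohort operating points (osteoporosis)
            (95.7, 78.0, 23, 82, 81.9),
            (87.0, 81.7, 23, 82, 82.9),
            (87.0, 76.8, 23, 82, 79.0),
            (95.7, 75.6, 23, 82, 80.0),
            # published test-cohort operating points
            (100.0, 73.8, 14, 61, 78.7),
            (85.7, 83.6, 14, 61, 84.0),
            (84.4, 83.7, 32, 43, 84.0),
        ],
    )
    def test_reconstructs_published_cells(self, sens, spec, n_pos, n_neg, expected):
        assert accuracy_from_sens_spec(sens, spec, n_pos, n_neg) == expected

    def test_bad_sizes_rejected(self):
        with pytest.raises(ValueError):
            accuracy_from_sens_spec(90.0, 90.0, 0, 10)


class TestCorrelationAndRegression:
    def test_exact_linear_relations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert pearson_r(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson_r(x, -x)[0] == pytest.approx(-1.0)

    def test_five_point_hand_set(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        # direct product-moment formula
        r_oracle = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        r, p = pearson_r(x, y)
        assert r == pytest.approx(r_oracle)
        assert 0.0 < p < 1.0

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_regression_recovers_exact_line(self):
        ages = np.array([40.0, 50.0, 60.0, 70.0, 45.0, 55.0])
        sex = np.array(["F", "F", "F", "M", "M", "M"])
        bmd = np.where(sex == "F", 0.4 - 0.005 * ages, 0.35 - 0.003 * ages)
        fit = age_regression(ages, bmd, sex)
        assert fit["F"]["slope"] == pytest.approx(-0.005)
        assert fit["M"]["slope"] == pytest.approx(-0.003)
        assert fit["F"]["intercept"] == pytest.approx(0.4)

    def test_degenerate_age_rejected(self):
        with pytest.raises(ValueError):
            age_regression([50.0] * 4, [0.1] * 4, ["F"] * 4)


class TestGroupComparisons:
    @staticmethod
    def _cohort(values_by_group):
        rows = []
        for g, vals in values_by_group.items():
            for v in vals:
                rows.append({"group": g, "vbmd_L1": v})
        return pd.DataFrame(rows)

    def test_identical_groups_not_significant(self):
        vals = [0.1, 0.12, 0.14, 0.16]
        cohort = self._cohort(
            {"normal": vals, "osteopenia": vals, "osteoporosis": vals}
        )
        table = pairwise_group_tests(cohort, "L1")
        assert np.allclose(table["p_value"], 1.0)

    def test_separated_groups_all_significant(self, rng):
        cohort = self._cohort(
            {
                "normal": rng.normal(0.175, 0.02, 20),
                "osteopenia": rng.normal(0.115, 0.02, 20),
                "osteoporosis": rng.normal(0.062, 0.02, 20),
            }
        )
        assert (pairwise_group_tests(cohort, "L1")["p_value"] < 0.01).all()

    def test_undersized_group_rejected(self):
        cohort = self._cohort(
            {"normal": [0.1, 0.2], "osteopenia": [0.1, 0.2], "osteoporosis": [0.1]}
        )
        with pytest.raises(ValueError):
            pairwise_group_tests(cohort, "L1")
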