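import math

import numpy as np
import pytest

from ac_cellscan.errors import FitError
from ac_cellscan.grading import (
    CalibrationModel,
    fit_log_curve,
    kruskal_wallis,
    loocv,
    predict_grade,
    published_model,
    spearman_rho,
    split_train_test,
)


def _rank(values):
    """Average ranks, brute force (oracle helper)."""
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


class TestFitLogCurve:
    def test_exact_recovery_of_reference_coefficients(self):
        model = published_model()
        points = [(x, model.slope * math.log(x) + model.intercept) for x in (2, 5, 20, 100)]
        fit = fit_log_curve(points)
        assert fit.slope == pytest.approx(model.slope, abs=1e-12)
        assert fit.intercept == pytest.approx(model.intercept, abs=1e-12)

    def test_two_point_closed_form(self):
        fit = fit_log_curve([(1, 0.0), (math.e**2, 2.0)])
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_zero_counts_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            fit = fit_log_curve([(0, 3.0), (1, 0.0), (math.e, 1.0)])
        assert fit.slope == pytest.approx(1.0)
        assert any("zero-count" in r.message for r in caplog.records)

    def test_too_few_points_raises(self):
        with pytest.raises(FitError):
            fit_log_curve([(0, 1.0), (5, 2.0)])

    def test_identical_counts_degenerate(self):
        with pytest.raises(FitError):
            fit_log_curve([(7, 1.0), (7, 2.0), (7, 3.0)])


class TestPredictGrade:
    def test_count_one_returns_intercept(self):
        assert predict_grade(published_model(), 1) == pytest.approx(0.2276)

    def test_efold_increase_adds_the_slope(self):
        model = published_model()
        for x in (1, 10, 57):
            delta = predict_grade(model, math.e * x) - predict_grade(model, x)
            assert delta == pytest.approx(0.4347)

    def test_zero_count_maps_to_zero_grade(self):
        assert predict_grade(published_model(), 0) == 0.0

    def test_clip_constrains_to_sun_range(self):
        model = CalibrationModel(slope=1.0, intercept=0.0)
        assert predict_grade(model, 10**6, clip=True) == 4.0
        assert predict_grade(CalibrationModel(1.0, -5.0), 1, clip=True) == 0.0

    def test_monotone_in_count_for_positive_slope(self):
        model = published_model()
        preds = [predict_grade(model, x) for x in range(1, 200)]
        assert all(a <= b for a, b in zip(preds, preds[1:]))


class TestSpearman:
    def test_perfect_monotone_association(self):
        rho, _ = spearman_rho([1, 2, 3, 7, 20], [0.1, 0.5, 0.7, 2.0, 9.0])
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_rho([1, 2, 3, 7, 20], [9.0, 2.0, 0.7, 0.5, 0.1])
        assert rho == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # d^2 = (1,1,1,1,0) -> rho = 1 - 6*4/(5*24) = 0.8
        xs, ys = [1, 2, 3, 4, 5], [2, 1, 4, 3, 5]
        d2 = sum((rx - ry) ** 2 for rx, ry in zip(_rank(xs), _rank(ys)))
        oracle = 1 - 6 * d2 / (5 * (25 - 1))
        rho, _ = spearman_rho(xs, ys)
        assert oracle == pytest.approx(0.8)
        assert rho == pytest.approx(oracle)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        xs = rng.random(20)
        ys = rng.random(20)
        rho0, _ = spearman_rho(xs, ys)
        rho1, _ = spearman_rho(np.exp(5 * xs), ys**3 + 2)
        assert rho1 == pytest.approx(rho0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])


class TestKruskalWallis:
    def test_identical_groups_give_zero(self):
        h, p = kruskal_wallis([[5, 5, 5], [5, 5, 5]])
        assert h == 0.0 and p == 1.0

    def test_matches_rank_formula_without_ties(self):
        groups = [[1, 2, 3], [10, 11, 12]]
        pooled = [v for g in groups for v in g]
        ranks = _rank(pooled)
        n = len(pooled)
        start, h_oracle = 0, 0.0
        for g in groups:
            r_sum = sum(ranks[start : start + len(g)])
            h_oracle += r_sum**2 / len(g)
            start += len(g)
        h_oracle = 12 / (n * (n + 1)) * h_oracle - 3 * (n + 1)
        h, p = kruskal_wallis(groups)
        assert h == pytest.approx(h_oracle)
        assert 0 < p < 0.1

    def test_matches_tie_corrected_oracle(self):
        groups = [[1, 1, 2], [2, 2, 3], [3, 4, 4]]
        pooled = [v for g in groups for v in g]
        ranks = _rank(pooled)
        n = len(pooled)
        start, h_oracle = 0, 0.0
        for g in groups:
            r_sum = sum(ranks[start : start + len(g)])
            h_oracle += r_sum**2 / len(g)
            start += len(g)
        h_oracle = 12 / (n * (n + 1)) * h_oracle - 3 * (n + 1)
        from collections import Counter

        ties = Counter(pooled).values()
        correction = 1 - sum(t**3 - t for t in ties) / (n**3 - n)
        h_oracle /= correction
        h, _ = kruskal_wallis(groups)
        assert h == pytest.approx(h_oracle)


class TestSplit:
    def _eyes(self, n=48):
        grades = ([0.0] * 13 + [0.5] * 6 + [1.0] * 12 + [2.0] * 10 + [3.0] * 7)[:n]
        return [(i + 1, g) for i, g in enumerate(grades)]

    def test_partition_is_disjoint_and_exhaustive(self):
        eyes = self._eyes()
        train, test = split_train_test(eyes, n_train=26, seed=3)
        assert len(train) == 26 and len(test) == 22
        assert sorted(train + test) == sorted(eyes)
        assert not set(train) & set(test)

    def test_same_seed_reproduces_partition(self):
        eyes = self._eyes()
        assert split_train_test(eyes, 26, seed=5) == split_train_test(eyes, 26, seed=5)

    def test_different_seed_changes_partition(self):
        eyes = self._eyes()
        assert split_train_test(eyes, 26, seed=5) != split_train_test(eyes, 26, seed=6)

    def test_stratification_keeps_grade_balance(self):
        eyes = self._eyes()
        train, _ = split_train_test(eyes, 26, seed=1)
        frac = 26 / 48
        for grade, total in [(0.0, 13), (0.5, 6), (1.0, 12), (2.0, 10), (3.0, 7)]:
            got = sum(1 for _, g in train if g == grade)
            assert abs(got - total * frac) <= 1.0

    def test_invalid_n_train_rejected(self):
        with pytest.raises(ValueError):
            split_train_test(self._eyes(), 0, seed=0)
        with pytest.raises(ValueError):
            split_train_test(self._eyes(), 48, seed=0)


class TestLoocv:
    def test_noise_free_log_curve_recovered_exactly(self):
        model = published_model()
        counts = [2, 3, 5, 9, 17, 33, 65, 120, 260, 410]
        eyes = [(x, predict_grade(model, x)) for x in counts]
        report = loocv(eyes)
        assert report.spearman_rho == pytest.approx(1.0)
        for _, observed, _, predicted in report.per_eye:
            assert predicted == pytest.approx(observed, abs=1e-9)

    def test_fold_count_equals_n(self):
        eyes = [(2, 0.5), (10, 1.0), (100, 2.0)]
        report = loocv(eyes)
        assert report.n == 3 and len(report.per_eye) == 3

    def test_order_invariance_of_predictions(self):
        rng = np.random.default_rng(8)
        counts = rng.integers(1, 400, size=12)
        eyes = [(int(x), float(published_model().slope * math.log(x))) for x in counts]
        ids = [f"e{i}" for i in range(12)]
        fwd = loocv(eyes, eye_ids=ids)
        perm = list(reversed(range(12)))
        rev = loocv([eyes[i] for i in perm], eye_ids=[ids[i] for i in perm])
        fwd_map = {row[0]: row[3] for row in fwd.per_eye}
        rev_map = {row[0]: row[3] for row in rev.per_eye}
        assert fwd_map == pytest.approx(rev_map)

    def test_too_few_eyes_rejected(self):
        with pytest.raises(ValueError):
            loocv([(2, 0.5), (10, 1.0)])
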