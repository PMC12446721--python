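"""AUCROC, bootstrap distribution, p-value and CI machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm
from sklearn.metrics import roc_auc_score

from screenval import rocboot
from conftest import brute_force_auc


class TestAuc:
    def test_constant_scores_give_chance_performance(self):
        assert rocboot.auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_perfect_separation_gives_one(self):
        assert rocboot.auc([1, 2, 10, 11], [0, 0, 1, 1]) == 1.0

    def test_four_point_tie_free_example(self):
        # pairs: wins {4>3, 4>2}, losses {1<3, 1<2} -> 2/4
        assert rocboot.auc([3, 1, 2, 4], [0, 1, 0, 1]) == 0.5

    def test_matches_pairwise_oracle_on_random_instances(self):
        rng = np.random.default_rng(1234)
        for _ in range(300):
            n = rng.integers(4, 21)
            labels = np.zeros(n, dtype=int)
            labels[: rng.integers(1, n)] = 1
            rng.shuffle(labels)
            # integer scores force ties, exercising the half-credit path
            scores = rng.integers(0, 6, size=n).astype(float)
            assert rocboot.auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(5)
        scores = rng.integers(0, 27, size=200).astype(float)
        labels = rng.integers(0, 2, size=200)
        labels[0], labels[1] = 0, 1
        assert rocboot.auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_complement_symmetry(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=50)
        labels = np.r_[np.ones(10, dtype=int), np.zeros(40, dtype=int)]
        assert rocboot.auc(-scores, labels) == pytest.approx(
            1.0 - rocboot.auc(scores, labels), abs=1e-12
        )

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.integers(0, 26), min_size=4, max_size=30), st.data())
    def test_monotone_transform_invariance(self, raw_scores, data):
        n = len(raw_scores)
        labels = np.array(data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda ls: 0 < sum(ls) < n
            )
        ))
        scores = np.asarray(raw_scores, dtype=float)
        transformed = np.exp(scores / 5.0) + 3.0  # strictly increasing
        assert rocboot.auc(scores, labels) == pytest.approx(
            rocboot.auc(transformed, labels), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            rocboot.auc([1.0, 2.0], [1, 1])

    def test_binormal_closed_form_recovery(self):
        # true AUC = Phi(d / sqrt(2)); at d = sqrt(2) * Phi^-1(0.8) it is 0.8
        d = np.sqrt(2.0) * norm.ppf(0.8)
        rng = np.random.default_rng(99)
        n = 2000
        scores = np.r_[rng.normal(d, 1, n), rng.normal(0, 1, n)]
        labels = np.r_[np.ones(n, dtype=int), np.zeros(n, dtype=int)]
        est = rocboot.auc(scores, labels)
        # Hanley-McNeil style SE bound for a Monte-Carlo band
        se = np.sqrt(0.8 * 0.2 / n)
        assert abs(est - 0.8) < 3 * se


class TestRocCurve:
    def test_curve_area_equals_pairwise_auc(self):
        rng = np.random.default_rng(11)
        scores = rng.integers(0, 8, size=30).astype(float)
        labels = np.r_[np.ones(10, dtype=int), np.zeros(20, dtype=int)]
        rng.shuffle(labels)
        curve = rocboot.roc_points(scores, labels)
        assert curve.area() == pytest.approx(rocboot.auc(scores, labels), abs=1e-12)

    def test_perfect_separation_passes_through_topleft(self):
        curve = rocboot.roc_points([0.0, 1.0, 10.0, 11.0], [0, 0, 1, 1])
        assert any((f == 0.0 and t == 1.0) for f, t in zip(curve.fpr, curve.tpr))

    def test_constant_scores_collapse_to_endpoints(self):
        curve = rocboot.roc_points([2.0, 2.0, 2.0], [0, 1, 0])
        assert len(curve.fpr) == 2
        assert curve.area() == pytest.approx(0.5)

    def test_coordinates_monotone_from_origin_to_corner(self):
        rng = np.random.default_rng(12)
        scores = rng.normal(size=40)
        labels = np.r_[np.ones(15, dtype=int), np.zeros(25, dtype=int)]
        curve = rocboot.roc_points(scores, labels)
        assert curve.fpr[0] == 0 and curve.tpr[0] == 0
        assert curve.fpr[-1] == 1 and curve.tpr[-1] == 1
        assert (np.diff(curve.fpr) >= 0).all() and (np.diff(curve.tpr) >= 0).all()


class TestBootstrap:
    def test_single_iteration_returns_auc_of_resample(self):
        res = rocboot.bootstrap_auc([1, 2, 3, 4], [0, 0, 1, 1], n_boot=1, seed=3)
        assert len(res) == 1
        assert 0.0 <= res.values[0] <= 1.0

    def test_perfect_separation_bootstraps_to_one(self):
        res = rocboot.bootstrap_auc(
            [0, 1, 2, 10, 11, 12], [0, 0, 0, 1, 1, 1], n_boot=200, seed=4
        )
        assert (res.values == 1.0).all()

    def test_stratified_mean_near_point_estimate(self):
        rng = np.random.default_rng(21)
        scores = np.r_[rng.normal(1.2, 1, 50), rng.normal(0, 1, 450)]
        labels = np.r_[np.ones(50, dtype=int), np.zeros(450, dtype=int)]
        point = rocboot.auc(scores, labels)
        res = rocboot.bootstrap_auc(scores, labels, n_boot=1000, seed=22)
        assert abs(res.values.mean() - point) < 0.02

    def test_simple_scheme_reports_redraws(self):
        # tiny sample with one positive: single-class joint resamples are common
        res = rocboot.bootstrap_auc([3, 1, 2], [1, 0, 0], n_boot=300, seed=5, scheme="simple")
        assert res.n_single_class_redraws > 0
        assert len(res.values) == 300

    def test_reproducible_under_seed(self):
        args = ([1, 5, 2, 4, 3, 6], [0, 1, 0, 1, 0, 1])
        a = rocboot.bootstrap_auc(*args, n_boot=50, seed=9)
        b = rocboot.bootstrap_auc(*args, n_boot=50, seed=9)
        np.testing.assert_array_equal(a.values, b.values)


class TestPValues:
    def test_denominator_is_nboot_plus_one(self):
        boot = np.full(1000, 0.9)
        p = rocboot.p_threshold_one_sided(boot, 0.8, direction="below")
        assert p.denominator == 1001
        assert p.value == pytest.approx(1000 / 1001)
        assert not p.at_floor

    def test_zero_count_renders_as_floor(self):
        boot = np.full(1000, 0.7)  # nothing crosses the threshold
        p = rocboot.p_threshold_one_sided(boot, 0.8, direction="below")
        assert p.at_floor
        assert str(p) == "<0.001"
        assert p.value == pytest.approx(1 / 1001)

    def test_partial_count_arithmetic(self):
        boot = np.r_[np.full(250, 0.9), np.full(750, 0.7)]
        p = rocboot.p_threshold_one_sided(boot, 0.8, direction="below")
        assert p.value == pytest.approx(250 / 1001)

    def test_direction_above_mirrors(self):
        boot = np.r_[np.full(250, 0.9), np.full(750, 0.7)]
        p = rocboot.p_threshold_one_sided(boot, 0.8, direction="above")
        assert p.value == pytest.approx(750 / 1001)

    def test_two_sided_doubles_smaller_tail(self):
        boot = np.r_[np.full(600, 0.7), np.full(400, 0.9)]
        p = rocboot.p_threshold_two_sided(boot, 0.8)
        assert p.value == pytest.approx(2 * 400 / 1001)

    def test_two_sided_floor_when_all_above(self):
        boot = np.full(1000, 0.95)
        p = rocboot.p_threshold_two_sided(boot, 0.8)
        assert p.at_floor
        assert p.value == pytest.approx(2 / 1001)

    def test_two_sided_near_one_when_median_at_threshold(self):
        boot = np.r_[np.full(500, 0.75), np.full(500, 0.85)]
        p = rocboot.p_threshold_two_sided(boot, 0.8)
        assert p.value > 0.95

    def test_p_values_never_zero_nor_above_one(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            boot = rng.uniform(0, 1, size=rng.integers(1, 200))
            thr = rng.uniform(0, 1)
            for p in (
                rocboot.p_threshold_one_sided(boot, thr, "below"),
                rocboot.p_threshold_one_sided(boot, thr, "above"),
                rocboot.p_threshold_two_sided(boot, thr),
            ):
                assert 0.0 < p.value <= 1.0


class TestBootstrapCi:
    def test_constant_vector_zero_width(self):
        assert rocboot.bootstrap_ci(np.full(100, 0.8)) == (0.8, 0.8)

    def test_linear_interpolation_quantiles(self):
        boot = np.arange(0.1, 1.05, 0.1)
        low, high = rocboot.bootstrap_ci(boot, level=0.8)
        assert low == pytest.approx(0.19)
        assert high == pytest.approx(0.91)

    def test_ordering_property(self):
        rng = np.random.default_rng(41)
        for _ in range(1000):
            boot = rng.uniform(0, 1, size=rng.integers(1, 50))
            low, high = rocboot.bootstrap_ci(boot)
            assert low <= high


class TestRocTest:
    def test_report_fields_consistent(self):
        rng = np.random.default_rng(51)
        scores = np.r_[rng.normal(2, 1, 30), rng.normal(0, 1, 270)]
        labels = np.r_[np.ones(30, dtype=int), np.zeros(270, dtype=int)]
        res = rocboot.roc_test(scores, labels, n_boot=300, seed=8)
        assert res.n_positives == 30 and res.n_negatives == 270
        assert res.ci[0] <= res.ci[1]
        assert 0 < res.p_one_sided.value <= 1
        assert 0 < res.p_two_sided.value <= 1

    def test_changing_n_boot_keeps_point_estimate(self):
        scores = [1, 5, 2, 4, 3, 6, 2, 5]
        labels = [0, 1, 0, 1, 0, 1, 0, 1]
        a = rocboot.roc_test(scores, labels, n_boot=10, seed=1)
        b = rocboot.roc_test(scores, labels, n_boot=200, seed=1)
        assert a.auc == b.auc
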