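import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emrisk.evaluation import (
    FoldMetrics,
    UndefinedMetricWarning,
    aggregate,
    compute_metrics,
    cross_validate,
    grouped_control_evaluation,
    pooled_metrics,
    stratified_kfold,
)


class TestStratifiedKFold:
    def test_divisible_stratification_is_exact(self):
        labels = np.array(["case"] * 30 + ["control"] * 70)
        folds = stratified_kfold(labels, 10, seed=0)
        for f in range(10):
            assert np.sum((folds == f) & (labels == "case")) == 3
            assert np.sum((folds == f) & (labels == "control")) == 7

    def test_remainder_spread_within_one(self):
        labels = np.array(["case"] * 13 + ["control"] * 87)
        folds = stratified_kfold(labels, 10, seed=3)
        case_counts = [
            np.sum((folds == f) & (labels == "case")) for f in range(10)
        ]
        assert max(case_counts) - min(case_counts) <= 1

    def test_deterministic_given_seed(self):
        labels = np.array(["case"] * 5 + ["control"] * 15)
        a = stratified_kfold(labels, 4, seed=9)
        b = stratified_kfold(labels, 4, seed=9)
        assert (a == b).all()

    def test_partition_property(self):
        labels = np.array(["case"] * 7 + ["control"] * 11)
        folds = stratified_kfold(labels, 5, seed=1)
        assert folds.shape == labels.shape
        assert set(folds) <= set(range(5))

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            stratified_kfold(["case", "control"], 3, seed=0)

    @given(
        n_case=st.integers(1, 40),
        n_control=st.integers(1, 60),
        k=st.integers(2, 10),
        seed=st.integers(0, 2**20),
    )
    @settings(max_examples=60, deadline=None)
    def test_per_class_balance_for_all_mixes(self, n_case, n_control, k, seed):
        if k > n_case + n_control:
            return
        labels = np.array(["case"] * n_case + ["control"] * n_control)
        folds = stratified_kfold(labels, k, seed=seed)
        for cls in ("case", "control"):
            counts = [
                int(np.sum((folds == f) & (labels == cls))) for f in range(k)
            ]
            assert max(counts) - min(counts) <= 1
            assert sum(counts) == int(np.sum(labels == cls))


class TestComputeMetrics:
    def test_sensitivity_is_tp_over_cp(self):
        truth = ["case"] * 10 + ["control"] * 4
        pred = ["case"] * 5 + ["control"] * 5 + ["control"] * 4
        m = compute_metrics(truth, pred)
        assert m.true_positive == 5 and m.condition_positive == 10
        assert m.sensitivity == pytest.approx(0.5)

    def test_perfect_prediction(self):
        truth = ["case", "control", "case"]
        m = compute_metrics(truth, truth)
        assert m.sensitivity == m.specificity == m.accuracy == 1.0

    def test_balanced_accuracy_is_mean_of_sens_and_spec(self):
        # CP = CN = 10, sens 0.8, spec 0.6 -> accuracy 0.7
        truth = ["case"] * 10 + ["control"] * 10
        pred = (["case"] * 8 + ["control"] * 2
                + ["control"] * 6 + ["case"] * 4)
        m = compute_metrics(truth, pred)
        assert m.sensitivity == pytest.approx(0.8)
        assert m.specificity == pytest.approx(0.6)
        assert m.accuracy == pytest.approx(0.7)
        assert m.accuracy == pytest.approx(
            (m.sensitivity + m.specificity) / 2
        )

    def test_single_class_truth_flags_undefined_metric(self):
        with pytest.warns(UndefinedMetricWarning):
            m = compute_metrics(["case", "case"], ["case", "control"])
        assert np.isnan(m.specificity)
        assert m.sensitivity == pytest.approx(0.5)

    def test_permutation_invariant(self, rng):
        truth = np.array(["case"] * 6 + ["control"] * 9)
        pred = truth.copy()
        pred[[0, 7]] = ["control", "case"]
        perm = rng.permutation(truth.size)
        a = compute_metrics(truth, pred)
        b = compute_metrics(truth[perm], pred[perm])
        assert a == b

    def test_count_invariants_enforced(self):
        with pytest.raises(ValueError):
            FoldMetrics(5, 0, 4, 0, 1.0, 0.0, 0.5)


class TestAggregate:
    def _fm(self, acc):
        return FoldMetrics(0, 0, 0, 0, acc, acc, acc)

    def test_two_point_hand_case(self):
        res = aggregate([self._fm(2.0), self._fm(4.0)])
        assert res.mean_accuracy == pytest.approx(3.0)
        assert res.sd_accuracy == pytest.approx(1.0)  # population SD

    def test_constant_folds_have_zero_sd(self):
        res = aggregate([self._fm(0.8)] * 5)
        assert res.sd_accuracy == 0.0

    def test_population_sd_divides_by_n(self):
        res = aggregate([self._fm(x) for x in (1.0, 2.0, 3.0, 4.0)])
        assert res.sd_accuracy == pytest.approx(np.sqrt(1.25))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate([])

    def test_pooled_metrics_sum_counts(self):
        folds = [FoldMetrics(3, 4, 5, 5, 0.6, 0.8, 0.7),
                 FoldMetrics(5, 2, 5, 5, 1.0, 0.4, 0.7)]
        p = pooled_metrics(folds)
        assert p.true_positive == 8 and p.condition_positive == 10
        assert p.sensitivity == pytest.approx(0.8)


class TestCrossValidate:
    @pytest.fixture
    def signal_matrix(self):
        """Cases carry a dense block of 6 codes that controls rarely have."""
        rng = np.random.default_rng(21)
        n_case, n_control, m = 30, 30, 20
        PD = (rng.random((n_case + n_control, m)) < 0.15).astype(float)
        PD[:n_case, :6] = (rng.random((n_case, 6)) < 0.9).astype(float)
        labels = np.array(["case"] * n_case + ["control"] * n_control)
        return PD, labels

    def test_folds_partition_patients(self, signal_matrix):
        PD, labels = signal_matrix
        res = cross_validate(PD, labels, 3, n_folds=5, seed=2, max_iter=60)
        assert sum(
            f.condition_positive + f.condition_negative for f in res.per_fold
        ) == len(labels)

    def test_inductive_beats_chance_on_planted_signal(self, signal_matrix):
        PD, labels = signal_matrix
        res = cross_validate(PD, labels, 3, n_folds=5, seed=2, max_iter=60)
        assert res.mean_accuracy > 0.7

    def test_transductive_mode_runs(self, signal_matrix):
        PD, labels = signal_matrix
        res = cross_validate(
            PD, labels, 3, n_folds=5, seed=2, mode="transductive",
            max_iter=60,
        )
        assert 0.0 <= res.mean_accuracy <= 1.0

    def test_unknown_mode_rejected(self, signal_matrix):
        PD, labels = signal_matrix
        with pytest.raises(ValueError):
            cross_validate(PD, labels, 3, mode="bogus")

    def test_deterministic_given_seed(self, signal_matrix):
        PD, labels = signal_matrix
        a = cross_validate(PD, labels, 3, n_folds=4, seed=5, max_iter=40)
        b = cross_validate(PD, labels, 3, n_folds=4, seed=5, max_iter=40)
        assert a.mean_accuracy == b.mean_accuracy
        assert a.per_fold == b.per_fold


class TestGroupedControls:
    def test_groups_are_disjoint_and_cover(self, rng):
        PD_cases = (rng.random((6, 10)) < 0.5).astype(float)
        PD_controls = (rng.random((6, 10)) < 0.5).astype(float)
        ge = grouped_control_evaluation(
            PD_cases, PD_controls, rank=2, n_groups=2, group_size=3,
            n_folds=2, seed=0, max_iter=30,
        )
        assert len(ge.results) == 2
        assert set(ge.grand.index) == {"sensitivity", "specificity",
                                       "accuracy"}

    def test_insufficient_controls_rejected(self, rng):
        PD = (rng.random((4, 5)) < 0.5).astype(float)
        with pytest.raises(ValueError):
            grouped_control_evaluation(
                PD, PD, rank=2, n_groups=3, group_size=2
            )

    def test_same_seed_reproduces_grouping(self, rng):
        PD_cases = (rng.random((6, 10)) < 0.5).astype(float)
        PD_controls = (rng.random((8, 10)) < 0.5).astype(float)
        kwargs = dict(rank=2, n_groups=2, group_size=4, n_folds=2,
                      seed=4, max_iter=30)
        a = grouped_control_evaluation(PD_cases, PD_controls, **kwargs)
        b = grouped_control_evaluation(PD_cases, PD_controls, **kwargs)
        assert a.grand.equals(b.grand)
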