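"""Training loop, cross-validation, splits, learning curve, HL test,
and the learner comparison table."""

import numpy as np
import pytest

from tmbserval.cohort import Cohort, PatientRecord, SubgroupBag
from tmbserval.losses import LossSpec
from tmbserval.network import init_network
from tmbserval.train_eval import (
    TrainConfig,
    compare_learners,
    evaluate_loss,
    hosmer_lemeshow,
    kfold_cv,
    learning_curve,
    split_train_test,
    train,
)


def _strong_signal_cohort(n_per_bag=20, seed=0):
    """Bag labels a monotone function of a well-separated feature shift."""
    rng = np.random.default_rng(seed)
    pats, bags = {}, []
    targets = [(0.2, 0.25), (0.5, 0.55), (0.8, 0.85)]
    for m, target in enumerate(targets):
        ids = []
        for i in range(n_per_bag):
            pid = f"p{m}_{i}"
            x = rng.normal(loc=2.0 * m, scale=0.5, size=3)
            pats[pid] = PatientRecord(pid, x, 0.5, 10.0, 1)
            ids.append(pid)
        bags.append(SubgroupBag(f"G{m}", ids, np.asarray(target)))
    return bags, pats


class TestTrain:
    def test_zero_learning_rate_leaves_weights_unchanged(self):
        bags, pats = _strong_signal_cohort()
        net = init_network(3, [8], 2, seed=0)
        before = net.get_params().copy()
        net, _ = train(net, bags, pats,
                       LossSpec(mode="vector_distance", metric="mean"),
                       TrainConfig(learning_rate=0.0, max_epochs=50, tolerance=0.0))
        np.testing.assert_array_equal(net.get_params(), before)

    def test_converges_on_strong_signal(self):
        bags, pats = _strong_signal_cohort()
        net = init_network(3, [8], 2, seed=0)
        net, report = train(net, bags, pats,
                            LossSpec(mode="vector_distance", metric="mean"),
                            TrainConfig(learning_rate=0.5, max_epochs=4000,
                                        tolerance=1e-4))
        assert report.final_train_loss < report.loss_trace[0]
        assert report.final_train_loss < 0.05

    def test_small_lr_never_increases_training_loss(self):
        bags, pats = _strong_signal_cohort()
        net = init_network(3, [8], 2, seed=1)
        _, report = train(net, bags, pats,
                          LossSpec(mode="vector_distance", metric="mean"),
                          TrainConfig(learning_rate=1e-3, max_epochs=200,
                                      tolerance=0.0))
        assert report.loss_trace[-1] <= report.loss_trace[0]

    def test_duplicated_bags_double_loss_and_match_at_half_lr(self):
        """Duplicating every bag doubles the summed loss and its gradient,
        so training the duplicate at lr/2 retraces the original at lr."""
        bags, pats = _strong_signal_cohort()
        spec = LossSpec(mode="vector_distance", metric="mean")
        dup = bags + [SubgroupBag(b.bag_id + "_copy", list(b.member_ids), b.label)
                      for b in bags]
        dup_pats = dict(pats)

        net_a = init_network(3, [8], 2, seed=0)
        net_a, rep_a = train(net_a, bags, pats, spec,
                             TrainConfig(learning_rate=0.1, max_epochs=100,
                                         tolerance=0.0))
        net_b = init_network(3, [8], 2, seed=0)
        net_b, rep_b = train(net_b, dup, dup_pats, spec,
                             TrainConfig(learning_rate=0.05, max_epochs=100,
                                         tolerance=0.0))
        np.testing.assert_allclose(net_a.get_params(), net_b.get_params(),
                                   rtol=1e-9, atol=1e-12)
        assert rep_b.loss_trace[0] == pytest.approx(2 * rep_a.loss_trace[0])

    def test_determinism_under_seed(self):
        bags, pats = _strong_signal_cohort()
        runs = []
        for _ in range(2):
            net = init_network(3, [8], 2, seed=7)
            net, _ = train(net, bags, pats,
                           LossSpec(mode="vector_distance", metric="median"),
                           TrainConfig(learning_rate=0.2, max_epochs=100))
            runs.append(net.get_params())
        np.testing.assert_array_equal(runs[0], runs[1])


def _mini_cohort(n_per_bag=12, n_bags=3, seed=0, label_dim=2):
    rng = np.random.default_rng(seed)
    pats, bags = [], []
    for m in range(n_bags):
        ids = []
        for i in range(n_per_bag):
            pid = f"p{m}_{i}"
            pats.append(PatientRecord(
                pid, rng.normal(loc=m, size=3), float(rng.integers(2)),
                float(rng.exponential(150)) + 1, 1,
            ))
            ids.append(pid)
        label = np.full(label_dim, (m + 1) / (n_bags + 1)) if label_dim > 1 \
            else float(m % 2)
        bags.append(SubgroupBag(f"G{m}", ids, label))
    return Cohort(pats, bags)


class TestSplits:
    def test_half_split_on_default_cohort(self, default_cohort):
        cohort, _ = default_cohort
        tr, te = split_train_test(cohort, 0.5, seed=0)
        assert abs(tr.n - 330) <= len(cohort.bags)
        assert tr.n + te.n == 660
        union = {p.patient_id for p in tr.patients} | {
            p.patient_id for p in te.patients
        }
        assert len(union) == 660
        # per-bag proportions within one patient of exact stratification
        for b_tr, b_all in zip(tr.bags, cohort.bags):
            assert abs(b_tr.n - 0.5 * b_all.n) <= 1

    def test_invalid_fraction(self, small_cohort):
        with pytest.raises(ValueError):
            split_train_test(small_cohort[0], 1.0)

    def test_leave_one_out_on_toy_cohort(self):
        cohort = _mini_cohort(n_per_bag=12, n_bags=1)
        spec = LossSpec(mode="vector_distance", metric="mean")
        cfg = TrainConfig(learning_rate=0.5, max_epochs=20)
        result = kfold_cv(cohort, spec, cfg, k=12, seed=0)
        assert len(result["fold_losses"]) == 12

    def test_folds_partition_cohort_and_are_seeded(self):
        from tmbserval.train_eval import _within_bag_folds

        cohort = _mini_cohort(n_per_bag=15, n_bags=3)
        f1 = _within_bag_folds(cohort.bags, 5, np.random.default_rng(3))
        f2 = _within_bag_folds(cohort.bags, 5, np.random.default_rng(3))
        assert f1 == f2
        assert set(f1) == {p.patient_id for p in cohort.patients}
        sizes = np.bincount(list(f1.values()), minlength=5)
        assert sizes.sum() == cohort.n and sizes.min() >= 1

    def test_small_bag_error_suggests_lower_k(self):
        cohort = _mini_cohort(n_per_bag=3, n_bags=2)
        with pytest.raises(ValueError, match="lower k"):
            kfold_cv(cohort, LossSpec(mode="vector_distance"), k=10)


class TestLearningCurve:
    def test_single_size_gives_single_row(self):
        cohort = _mini_cohort(n_per_bag=20, n_bags=3)
        spec = LossSpec(mode="vector_distance", metric="mean")
        cfg = TrainConfig(learning_rate=0.5, max_epochs=50)
        curve = learning_curve(cohort, sizes=[45], loss_spec=spec,
                               train_config=cfg, repeats=1)
        assert len(curve) == 1
        assert np.isfinite(curve[["train_loss", "validation_loss"]]).all().all()

    def test_sizes_column_monotone(self):
        cohort = _mini_cohort(n_per_bag=20, n_bags=3)
        spec = LossSpec(mode="vector_distance", metric="mean")
        cfg = TrainConfig(learning_rate=0.5, max_epochs=50)
        curve = learning_curve(cohort, sizes=[40, 20, 30], loss_spec=spec,
                               train_config=cfg, repeats=1)
        assert list(curve["size"]) == [20, 30, 40]

    def test_oversized_request_rejected(self):
        cohort = _mini_cohort(n_per_bag=10, n_bags=2)
        with pytest.raises(ValueError, match="exceeds"):
            learning_curve(cohort, sizes=[500],
                           loss_spec=LossSpec(mode="vector_distance"),
                           train_config=TrainConfig(max_epochs=5), repeats=1)


class TestHosmerLemeshow:
    def test_perfectly_calibrated_groups(self):
        # ten blocks of constant prediction whose observed counts match the
        # block means exactly -> statistic 0, p-value 1
        p = np.repeat(np.arange(1, 11) / 20.0, 20)
        y = np.concatenate([
            np.r_[np.ones(int(20 * pk)), np.zeros(20 - int(20 * pk))]
            for pk in np.arange(1, 11) / 20.0
        ])
        hl = hosmer_lemeshow(y, p, groups=10)
        assert hl.statistic == pytest.approx(0.0, abs=1e-12)
        assert hl.p_value == pytest.approx(1.0)

    def test_single_group_contribution(self):
        # middle block n=10, O=7, p-bar=0.5 contributes (7-5)^2/5+(3-5)^2/5=1.6
        p = np.r_[np.full(10, 0.2), np.full(10, 0.5), np.full(10, 0.8)]
        y = np.r_[np.ones(2), np.zeros(8), np.ones(7), np.zeros(3),
                  np.ones(8), np.zeros(2)]
        hl = hosmer_lemeshow(y, p, groups=3)
        assert hl.statistic == pytest.approx(1.6)
        assert hl.df == 1

    def test_degrees_of_freedom_regimes(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.05, 0.95, 400)
        y = rng.binomial(1, p).astype(float)
        assert hosmer_lemeshow(y, p, groups=10).df == 8
        assert hosmer_lemeshow(y, p, groups=20).df == 18

    def test_ties_kept_together(self):
        p = np.full(100, 0.5)
        y = np.r_[np.ones(50), np.zeros(50)]
        hl = hosmer_lemeshow(y, p, groups=10)
        assert hl.groups == 1  # all predictions tied -> one group

    def test_input_validation(self):
        with pytest.raises(ValueError, match="groups"):
            hosmer_lemeshow([1, 0, 1], [0.2, 0.5, 0.7], groups=2)
        with pytest.raises(ValueError, match="fewer"):
            hosmer_lemeshow([1, 0], [0.2, 0.5], groups=5)


class TestCompareLearners:
    @pytest.fixture(scope="class")
    def comparison(self, small_cohort):
        cohort, _ = small_cohort
        cfg = TrainConfig(learning_rate=0.2, momentum=0.9, max_epochs=1500)
        return compare_learners(cohort, seed=0, train_config=cfg)

    def test_table_shape(self, comparison):
        assert len(comparison) == 4 * 3 * 2  # learners x slices x group settings
        assert set(comparison["learner"]) == {"calibration", "mse", "cel", "svm"}

    def test_identical_seed_identical_table(self, small_cohort, comparison):
        cohort, _ = small_cohort
        cfg = TrainConfig(learning_rate=0.2, momentum=0.9, max_epochs=1500)
        again = compare_learners(cohort, seed=0, train_config=cfg)
        assert comparison.equals(again)

    def test_statistics_nonnegative_and_p_in_unit_interval(self, comparison):
        assert (comparison["hl_statistic"] >= 0).all()
        ok = comparison["p_value"].dropna()
        assert ((ok >= 0) & (ok <= 1)).all()


class TestEvaluateLoss:
    def test_trained_model_evaluates_lower_than_init(self):
        bags, pats = _strong_signal_cohort()
        spec = LossSpec(mode="vector_distance", metric="mean")
        net = init_network(3, [8], 2, seed=0)
        before = evaluate_loss(net, bags, pats, spec)
        net, _ = train(net, bags, pats, spec,
                       TrainConfig(learning_rate=0.5, max_epochs=500))
        assert evaluate_loss(net, bags, pats, spec) < before
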