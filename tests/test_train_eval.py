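"""Fold splitting, training contracts, metrics, LVH classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import elvmass as em
from elvmass.io_cohort import CohortError
from elvmass.model import small_model_spec
from elvmass.train_eval import (EvalReport, TrainConfig, apply_sex_scope,
                                bsa, c_statistic, lvh_metrics, make_folds,
                                train_fold)


class TestMakeFolds:
    def test_sorted_systematic_assignment(self):
        # LVM 10..100: fold 0 holds sorted ranks {0, 5} -> LVM {10, 60}
        lvm = np.array([10, 20, 30, 40, 50, 60, 70, 80, 90, 100.0])
        split = make_folds(lvm, k=5)
        fold0 = split.folds[0]["test"]
        assert sorted(lvm[fold0]) == [10.0, 60.0]

    def test_n5_k5_singletons(self):
        split = make_folds(np.arange(5.0), k=5)
        assert all(len(f["test"]) == 1 for f in split.folds)

    def test_rejects_too_small_n(self):
        with pytest.raises(CohortError):
            make_folds(np.arange(3.0), k=5)

    def test_even_lvm_distribution_across_folds(self):
        rng = np.random.default_rng(0)
        lvm = rng.gamma(8, 16, size=500)
        split = make_folds(lvm)
        means = [lvm[f["test"]].mean() for f in split.folds]
        assert (max(means) - min(means)) / np.mean(means) < 0.05

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=10, max_value=300),
           st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_partition_invariants_hold_for_random_inputs(self, n, seed):
        lvm = np.random.default_rng(seed).normal(130, 30, size=n)
        split = make_folds(lvm)
        sizes = [len(f["test"]) for f in split.folds]
        assert max(sizes) - min(sizes) <= 1
        for f in split.folds:
            tr, va, te = f["train"], f["val"], f["test"]
            assert len(np.intersect1d(tr, va)) == 0
            assert len(np.intersect1d(tr, te)) == 0
            assert len(np.intersect1d(va, te)) == 0
            assert len(tr) + len(va) + len(te) == n


class TestTraining:
    def test_history_shape(self, tiny_dataset):
        split = make_folds(tiny_dataset.lvm, k=5)
        config = TrainConfig(epochs=2, batch_size=8, patience=2, seed=0)
        _, hist = train_fold(small_model_spec(), tiny_dataset, split, 0,
                             config)
        assert len(hist["train_mae"]) == len(hist["val_mae"]) == 2
        assert 0 <= hist["best_epoch"] < 2

    def test_seeded_reproducibility(self, tiny_dataset):
        split = make_folds(tiny_dataset.lvm, k=5)
        spec = small_model_spec()
        config = TrainConfig(epochs=2, batch_size=8, patience=2, seed=3)
        _, h1 = train_fold(spec, tiny_dataset, split, 0, config)
        _, h2 = train_fold(spec, tiny_dataset, split, 0, config)
        assert h1["train_mae"] == h2["train_mae"]
        assert h1["val_mae"] == h2["val_mae"]

    def test_patience_zero_stops_at_first_non_improvement(self, tiny_dataset):
        split = make_folds(tiny_dataset.lvm, k=5)
        spec = small_model_spec()
        config = TrainConfig(epochs=50, batch_size=8, patience=0, seed=0)
        _, hist = train_fold(spec, tiny_dataset, split, 0, config)
        val = hist["val_mae"]
        # stopped as soon as an epoch failed to improve the best value
        assert len(val) < 50
        assert all(val[i] < min(val[:i]) for i in range(1, len(val) - 1))

    def test_empty_sex_partition_rejected(self, tiny_dataset):
        split = make_folds(tiny_dataset.lvm, k=5)
        only = tiny_dataset.sex[split.folds[0]["val"]]
        missing = "male" if "male" not in only else None
        # force an empty validation partition by an impossible scope
        import dataclasses

        all_female = np.array(["female"] * tiny_dataset.n)
        ds = dataclasses.replace(tiny_dataset, sex=all_female)
        spec = small_model_spec(sex_scope="male")
        with pytest.raises(CohortError, match="empty partition"):
            train_fold(spec, ds, split, 0, TrainConfig(epochs=1))

    def test_no_test_leakage_in_training_batches(self, tiny_dataset):
        # replacing all test-fold LVM values must not change training
        import dataclasses

        split = make_folds(tiny_dataset.lvm, k=5)
        spec = small_model_spec()
        config = TrainConfig(epochs=2, batch_size=8, patience=2, seed=1)
        test_idx = split.folds[0]["test"]
        lvm2 = tiny_dataset.lvm.copy()
        lvm2[test_idx] = 999.0
        ds2 = dataclasses.replace(tiny_dataset, lvm=lvm2)
        _, h1 = train_fold(spec, tiny_dataset, split, 0, config)
        _, h2 = train_fold(spec, ds2, split, 0, config)
        assert h1["train_mae"] == h2["train_mae"]
        assert h1["val_mae"] == h2["val_mae"]


class TestSexScope:
    def test_filters_to_target_sex(self):
        sex = np.array(["male", "female", "male", "female", "male"])
        idx = np.arange(5)
        np.testing.assert_array_equal(apply_sex_scope(idx, sex, "male"),
                                      [0, 2, 4])
        np.testing.assert_array_equal(apply_sex_scope(idx, sex, "female"),
                                      [1, 3])
        np.testing.assert_array_equal(apply_sex_scope(idx, sex, "all"), idx)


class TestEvaluate:
    def test_hand_worked_examples(self):
        assert em.evaluate([110.0], [100.0]) == pytest.approx((10.0, 10.0))
        assert em.evaluate([100.0, 200.0], [100.0, 200.0]) == (0.0, 0.0)
        assert em.evaluate([90.0, 220.0], [100.0, 200.0]) == \
            pytest.approx((15.0, 10.0))

    def test_nonpositive_truth_rejected(self):
        with pytest.raises(CohortError):
            em.evaluate([100.0], [0.0])


class TestIndexedLvm:
    def test_mosteller_exact_case(self):
        # height 180, weight 80: BSA = sqrt(14400/3600) = 2 exactly
        assert em.indexed_lvm(144.0, 180.0, 80.0) == pytest.approx(72.0)
        assert em.indexed_lvm(0.0001, 180.0, 80.0) == pytest.approx(0.0, abs=1e-3)

    def test_dubois_close_to_mosteller(self):
        m = bsa(180.0, 80.0, "mosteller")
        d = bsa(180.0, 80.0, "dubois")
        assert abs(d - m) / m < 0.03

    def test_nonpositive_anthropometrics_rejected(self):
        with pytest.raises(CohortError):
            em.indexed_lvm(100.0, 0.0, 80.0)


class TestClassifyLvh:
    @pytest.mark.parametrize("sex,indexed,expected", [
        ("male", 72.0, False),   # strict >
        ("male", 72.1, True),
        ("female", 55.0, False),
        ("female", 56.0, True),
    ])
    def test_threshold_strictness(self, sex, indexed, expected):
        assert em.classify_lvh(indexed, sex) is expected

    def test_unknown_sex_rejected(self):
        with pytest.raises(CohortError):
            em.classify_lvh(80.0, "unknown")


class TestCStatistic:
    def test_perfect_separation(self):
        assert c_statistic([3.0, 2.0, 1.0],
                           [True, True, False]) == 1.0

    def test_single_class_is_none(self):
        assert c_statistic([1.0, 2.0], [True, True]) is None

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(10, 200))
            scores = rng.normal(size=n).round(1)  # induce ties
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            pos, neg = scores[labels], scores[~labels]
            pairs = pos[:, None] - neg[None, :]
            brute = (np.sum(pairs > 0) + 0.5 * np.sum(pairs == 0)) \
                / (len(pos) * len(neg))
            assert c_statistic(scores, labels) == pytest.approx(brute)


class TestLvhMetrics:
    def test_perfect_predictions(self):
        # single sex: with pooled sexes the indexed-LVM score cannot be a
        # perfect separator of the sex-specific thresholds
        rng = np.random.default_rng(1)
        truth = rng.uniform(80, 250, size=50)
        h = rng.uniform(150, 190, size=50)
        w = rng.uniform(50, 100, size=50)
        sex = np.array(["male"] * 50)
        m = lvh_metrics(truth, truth, h, w, sex)
        assert m["c_statistic"] == 1.0
        for k in ("accuracy", "sensitivity", "specificity", "ppv", "f1"):
            assert m[k] == 1.0

    def test_confusion_arithmetic(self):
        # TP=47, FN=53, TN=89, FP=11 -> sens 0.47, spec 0.89
        sex = np.array(["male"] * 200)
        h = np.full(200, 180.0)
        w = np.full(200, 80.0)  # BSA exactly 2
        truth_pos = np.concatenate([np.full(100, 160.0),   # idx 80 > 72: LVH
                                    np.full(100, 120.0)])  # idx 60: normal
        pred = np.concatenate([np.full(47, 160.0), np.full(53, 120.0),
                               np.full(89, 120.0), np.full(11, 160.0)])
        m = lvh_metrics(pred, truth_pos, h, w, sex)
        assert m["sensitivity"] == pytest.approx(0.47)
        assert m["specificity"] == pytest.approx(0.89)
        assert m["confusion"] == {"tp": 47, "tn": 89, "fp": 11, "fn": 53}

    def test_single_class_reports_reason(self):
        sex = np.array(["male"] * 4)
        h = np.full(4, 180.0)
        w = np.full(4, 80.0)
        truth = np.full(4, 120.0)  # nobody has LVH
        m = lvh_metrics(truth, truth, h, w, sex)
        assert m["c_statistic"] is None
        assert "single-class" in m["c_statistic_reason"]


class TestRecalibration:
    def test_identity_and_affine(self):
        assert em.recalibrate_echo_lvm(123.0, (1.0, 0.0)) == 123.0
        assert em.recalibrate_echo_lvm(200.0, (0.8, 5.0)) == pytest.approx(165.0)

    def test_vector_preserves_length(self):
        out = em.recalibrate_echo_lvm(np.array([100.0, 200.0]), (0.9, 10.0))
        np.testing.assert_allclose(out, [100.0, 190.0])

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(CohortError):
            em.recalibrate_echo_lvm(100.0, (0.0, 5.0))


class TestEvalReport:
    def test_fold_aggregation(self):
        r = EvalReport.from_folds([10.0, 12.0], [9.0, 11.0], {}, n_test=100)
        assert r.mae == 11.0 and r.mape == 10.0
        assert r.mae_sd == pytest.approx(np.std([10, 12], ddof=1))
        assert r.to_dict()["n_test"] == 100
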