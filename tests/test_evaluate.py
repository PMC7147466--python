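"""Cross-validation machinery, Gmean scoring and subset search."""

import numpy as np
import pytest

from nhpredict.evaluate import (
    CVConfig,
    MetricSet,
    N_MASKS,
    StratificationError,
    effective_k,
    evaluate_subset,
    exhaustive_search,
    gmean,
    mask_to_columns,
    rank_results,
    stratified_folds,
)
from nhpredict.instances import GROUP_INDICES, GROUP_NAMES, N_FEATURES


class TestGmean:
    def test_published_row_value(self):
        assert round(gmean(100.00, 99.73), 2) == 99.86

    def test_zero_sensitivity_annihilates(self):
        assert gmean(0.0, 87.3) == 0.0

    def test_idempotent_on_equal_arguments(self):
        assert gmean(73.5, 73.5) == pytest.approx(73.5)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            gmean(101.0, 50.0)
        with pytest.raises(ValueError):
            gmean(50.0, -1.0)


class TestMetricSet:
    def test_derived_percentages(self):
        m = MetricSet(tp=16, fn=4, tn=32, fp=3)
        assert m.sn == pytest.approx(80.0)
        assert m.sp == pytest.approx(100 * 32 / 35)
        assert m.accuracy == pytest.approx(100 * 48 / 55)
        assert m.gmean == pytest.approx(np.sqrt(m.sn * m.sp))
        assert m.gmean <= max(m.sn, m.sp)


class TestStratifiedFolds:
    def test_divisible_case_exact_counts(self):
        y = np.array([1] * 20 + [0] * 35)
        folds = stratified_folds(y, 5, seed=3)
        for f in range(5):
            assert (y[folds == f] == 1).sum() == 4
            assert (y[folds == f] == 0).sum() == 7

    def test_too_small_class_raises(self):
        y = np.array([1] * 3 + [0] * 30)
        with pytest.raises(StratificationError, match="class 1"):
            stratified_folds(y, 5, seed=0)

    def test_proportions_within_one_instance_for_random_labels(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(20, 80))
            y = (rng.random(n) < 0.4).astype(int)
            if min((y == 0).sum(), (y == 1).sum()) < 5:
                continue
            folds = stratified_folds(y, 5, seed=int(rng.integers(1000)))
            for c in (0, 1):
                share = (y == c).sum() / 5
                for f in range(5):
                    assert abs(((y[folds == f]) == c).sum() - share) < 1

    def test_deterministic_in_seed(self):
        y = np.array([0, 1] * 20)
        np.testing.assert_array_equal(stratified_folds(y, 4, 9), stratified_folds(y, 4, 9))

    def test_effective_k_reduces_to_minority(self):
        assert effective_k(np.array([1] * 3 + [0] * 11), 5) == 3
        with pytest.raises(StratificationError):
            effective_k(np.array([1] + [0] * 10), 5)


def _planted(n=60, seed=0, sep_group="cob", sep=6.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, N_FEATURES))
    y = np.array([0, 1] * (n // 2))
    for col in GROUP_INDICES[sep_group]:
        X[:, col] = y * sep + rng.normal(0, 0.2, n)
    return X, y


class TestEvaluateSubset:
    def test_perfectly_separating_feature_gives_100(self):
        X, y = _planted()
        cv = CVConfig(k=5, repetitions=3, base_seed=0, classifier="svm")
        res = evaluate_subset(X, y, 1 << GROUP_NAMES.index("cob"), cv)
        assert res.mean_sn == pytest.approx(100.0)
        assert res.mean_sp == pytest.approx(100.0)
        assert res.mean_gmean == pytest.approx(100.0)

    def test_deterministic_under_fixed_config(self):
        X, y = _planted(seed=2)
        X += np.random.default_rng(5).normal(0, 2, X.shape)  # make it imperfect
        cv = CVConfig(k=4, repetitions=4, base_seed=7, classifier="svm")
        a = evaluate_subset(X, y, 0b101, cv)
        b = evaluate_subset(X, y, 0b101, cv)
        assert a.mean_gmean == b.mean_gmean
        assert [m.tp for m in a.per_repetition] == [m.tp for m in b.per_repetition]

    def test_mlp_deterministic_and_runs(self):
        X, y = _planted(n=40, seed=3)
        cv = CVConfig(k=3, repetitions=2, base_seed=1, classifier="mlp")
        a = evaluate_subset(X, y, 0b111, cv)
        b = evaluate_subset(X, y, 0b111, cv)
        assert a.mean_gmean == pytest.approx(b.mean_gmean)

    def test_pooled_counts_sum_to_dataset_size(self):
        X, y = _planted(n=50, seed=4)
        cv = CVConfig(k=5, repetitions=3, base_seed=0, classifier="svm")
        res = evaluate_subset(X, y, 0b11, cv)
        for m in res.per_repetition:
            assert m.n == len(y)

    def test_mean_gmean_is_mean_of_per_repetition_gmeans(self):
        X, y = _planted(n=50, seed=6)
        X += np.random.default_rng(8).normal(0, 3, X.shape)
        cv = CVConfig(k=5, repetitions=6, base_seed=0, classifier="svm")
        res = evaluate_subset(X, y, 0b1111, cv)
        assert res.mean_gmean == pytest.approx(np.mean([m.gmean for m in res.per_repetition]))
        # Jensen: mean of gmeans <= gmean of means
        assert res.mean_gmean <= np.sqrt(res.mean_sn * res.mean_sp) + 1e-9

    def test_scale_invariance_of_features(self):
        X, y = _planted(n=50, seed=9)
        X += np.random.default_rng(10).normal(0, 2, X.shape)
        cv = CVConfig(k=5, repetitions=3, base_seed=0, classifier="svm")
        a = evaluate_subset(X, y, 0b10101, cv)
        b = evaluate_subset(3.7 * X, y, 0b10101, cv)
        assert a.mean_gmean == pytest.approx(b.mean_gmean)


class TestExhaustiveSearch:
    def test_mask_space_is_2048(self):
        assert N_MASKS == 2048
        with pytest.raises(ValueError):
            mask_to_columns(0)
        with pytest.raises(ValueError):
            mask_to_columns(2048)
        assert len(mask_to_columns(2047)) == N_FEATURES

    def test_tie_broken_lexicographically(self):
        # two groups with identical, perfectly separating columns
        rng = np.random.default_rng(14)
        n = 40
        y = np.array([0, 1] * (n // 2))
        X = rng.normal(size=(n, N_FEATURES))
        sep = y * 5.0 + rng.normal(0, 0.1, n)
        X[:, GROUP_INDICES["iob"][0]] = sep
        X[:, GROUP_INDICES["cob"][0]] = sep
        cv = CVConfig(k=4, repetitions=2, base_seed=0, classifier="svm")
        results = [evaluate_subset(X, y, m, cv)
                   for m in (1 << GROUP_NAMES.index("iob"), 1 << GROUP_NAMES.index("cob"))]
        ranked = rank_results(results)
        assert ranked[0].mean_gmean == ranked[1].mean_gmean
        assert ranked[0].mask < ranked[1].mask
        assert ranked[0].groups == ("iob",)
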