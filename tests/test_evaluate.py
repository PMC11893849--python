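"""Screening statistics, ROC metrics, and the repeated-split SVM protocol."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from ppgemotion.evaluate import (
    correlation_matrix,
    roc_metrics,
    screen_features,
    svm_protocol,
    utest,
)


def _enumerated_two_sided_p(a, b):
    """Oracle: exact p by enumerating every assignment of pooled ranks."""
    pooled = sorted(list(a) + list(b))
    n = len(a)
    u_obs = sum(sum(x > y for y in b) for x in a)
    us = []
    for combo in itertools.combinations(range(len(pooled)), n):
        group_a = [pooled[i] for i in combo]
        group_b = [pooled[i] for i in range(len(pooled)) if i not in combo]
        us.append(sum(sum(x > y for y in group_b) for x in group_a))
    us = np.asarray(us)
    p = 2 * min(np.mean(us <= u_obs), np.mean(us >= u_obs))
    return min(1.0, p)


class TestUTest:
    def test_fully_separated_small_groups(self):
        res = utest([1, 2, 3], [4, 5, 6])
        assert res.u_stat == 0
        assert res.p_value == pytest.approx(0.1)
        assert res.method == "exact"

    def test_identical_samples_give_p_one(self):
        res = utest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_symmetry_and_u_complement(self, rng):
        for _ in range(10):
            a = rng.normal(size=8)
            b = rng.normal(0.5, size=11)
            r_ab, r_ba = utest(a, b), utest(b, a)
            assert r_ab.p_value == pytest.approx(r_ba.p_value, rel=1e-12)
            assert r_ab.u_stat + r_ba.u_stat == len(a) * len(b)

    def test_exact_p_matches_enumeration_oracle(self, rng):
        for na, nb in [(2, 3), (3, 3), (4, 2), (4, 5), (5, 5)]:
            a = rng.normal(size=na)
            b = rng.normal(0.8, size=nb)
            assert utest(a, b).p_value == pytest.approx(
                _enumerated_two_sided_p(a, b), abs=1e-12)

    def test_large_sample_matches_scipy_asymptotic(self, rng):
        a = rng.normal(size=200)
        b = rng.normal(0.25, size=210)
        ours = utest(a, b)
        ref = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_tied_data_matches_scipy(self, rng):
        a = rng.integers(0, 4, size=30).astype(float)
        b = rng.integers(1, 5, size=35).astype(float)
        ours = utest(a, b)
        ref = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert ours.method == "normal"
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            utest([], [1.0])

    def test_significance_stars(self):
        assert utest(np.arange(20.0), np.arange(20.0) + 30).stars == "***"


def _feature_frame(rng, n=60, shift=0.0):
    labels = np.r_[np.zeros(n // 2), np.ones(n // 2)]
    return pd.DataFrame({
        "subject_id": "s0",
        "label_arousal": np.where(labels == 1, "high", "low"),
        "signal": rng.normal(0, 1, n) + shift * labels,
        "noise": rng.normal(0, 1, n),
    })


class TestScreening:
    def test_shifted_feature_retained_noise_behaviour_calibrated(self, rng):
        kept_signal = kept_noise = 0
        reps = 60
        for _ in range(reps):
            table = _feature_frame(rng, n=120, shift=1.0)
            retained, _ = screen_features(table, "arousal", ["signal", "noise"])
            kept_signal += "signal" in retained
            kept_noise += "noise" in retained
        assert kept_signal == reps  # 1 SD shift at n=60/arm: essentially sure
        assert kept_noise <= 0.15 * reps  # type-I retention near alpha

    def test_constant_feature_not_retained(self, rng):
        table = _feature_frame(rng, shift=2.0)
        table["flat"] = 1.0
        retained, comps = screen_features(table, "arousal", ["flat"])
        assert retained == []
        assert comps[0].p_value == pytest.approx(1.0)

    def test_single_class_rejected(self, rng):
        table = _feature_frame(rng)
        table["label_arousal"] = "high"
        with pytest.raises(ValueError):
            screen_features(table, "arousal", ["signal"])

    def test_bh_correction_is_no_looser_than_raw(self, rng):
        table = _feature_frame(rng, n=80, shift=0.4)
        for k in range(8):
            table[f"n{k}"] = rng.normal(size=80)
        cols = ["signal"] + [f"n{k}" for k in range(8)]
        raw, comps = screen_features(table, "arousal", cols)
        adj, comps_adj = screen_features(table, "arousal", cols, correction="bh")
        assert set(adj) <= set(raw)
        # reported comparisons keep raw p-values under either mode
        assert [c.p_value for c in comps] == [c.p_value for c in comps_adj]


class TestROC:
    def test_perfect_scores(self):
        res = roc_metrics([0.0, 0.1, 0.9, 1.0], [0, 0, 1, 1], threshold=0.5)
        assert res.auc == 1.0
        assert res.accuracy == 1.0 and res.sensitivity == 1.0 and res.specificity == 1.0

    def test_label_independent_scores(self):
        # both classes see the identical score multiset -> chance level
        scores = np.tile([0.2, 0.8], 10)
        labels = np.repeat([0, 1], 10)
        assert roc_metrics(scores, labels).auc == pytest.approx(0.5)

    def test_four_point_worked_example(self):
        res = roc_metrics([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert res.auc == pytest.approx(0.75)

    def test_auc_equals_normalized_rank_sum(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 60))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.normal(size=n), 1)  # ties included
            auc = roc_metrics(scores, labels).auc
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            u = sum((p > neg).sum() + 0.5 * (p == neg).sum() for p in pos)
            assert auc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_metrics([0.1, 0.2], [1, 1])

    def test_f1_consistency(self, rng):
        scores = rng.normal(size=80)
        labels = (scores + rng.normal(scale=1.0, size=80) > 0).astype(int)
        res = roc_metrics(scores, labels)
        if res.precision + res.sensitivity > 0:
            expect = 2 * res.precision * res.sensitivity / (res.precision + res.sensitivity)
            assert res.f1 == pytest.approx(expect)


def _cluster_table(rng, n=500, delta=6.0):
    labels = rng.integers(0, 2, size=n)
    x = rng.normal(size=(n, 2)) + delta * labels[:, None]
    return pd.DataFrame({
        "subject_id": "s0",
        "label_arousal": np.where(labels == 1, "high", "low"),
        "f1": x[:, 0], "f2": x[:, 1],
    })


class TestSVMProtocol:
    def test_separable_clusters(self, rng):
        table = _cluster_table(rng)
        res = svm_protocol(table, "arousal", ["f1", "f2"], iterations=30, seed=5)
        assert res.auc >= 0.99
        assert res.accuracy >= 0.98

    def test_permuted_labels_chance_level(self, rng):
        table = _cluster_table(rng, delta=0.0)
        res = svm_protocol(table, "arousal", ["f1", "f2"], iterations=100, seed=5)
        assert 0.45 <= res.auc <= 0.55

    def test_seed_reproducibility(self, rng):
        table = _cluster_table(rng, n=120, delta=1.0)
        r1 = svm_protocol(table, "arousal", ["f1", "f2"], iterations=15, seed=9)
        r2 = svm_protocol(table, "arousal", ["f1", "f2"], iterations=15, seed=9)
        np.testing.assert_array_equal(r1.iteration_aucs, r2.iteration_aucs)

    def test_perfect_single_feature(self, rng):
        table = _cluster_table(rng, n=200, delta=0.0)
        table["oracle"] = (table["label_arousal"] == "high").astype(float)
        res = svm_protocol(table, "arousal", ["oracle"], iterations=10, seed=1)
        assert res.accuracy == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_loo_training_auc_mode(self, rng):
        table = _cluster_table(rng, n=60, delta=6.0)
        res = svm_protocol(table, "arousal", ["f1", "f2"], iterations=3,
                           seed=2, loo_training_auc=True)
        assert res.auc >= 0.99  # separable either way

    def test_subject_grouped_splits_keep_subjects_whole(self, rng):
        table = _cluster_table(rng, n=200, delta=4.0)
        table["subject_id"] = np.repeat([f"s{i}" for i in range(10)], 20)
        res = svm_protocol(table, "arousal", ["f1", "f2"], iterations=10,
                           seed=4, group_by_subject=True)
        assert 0.0 <= res.auc <= 1.0

    def test_minimum_size_guard(self, rng):
        table = _cluster_table(rng, n=10)
        with pytest.raises(ValueError):
            svm_protocol(table, "arousal", ["f1"], iterations=2, seed=0)


class TestCorrelation:
    def test_duplicated_feature_fully_correlated(self, rng):
        t = pd.DataFrame({"a": rng.normal(size=50)})
        t["b"] = t["a"]
        t["c"] = rng.normal(size=50)
        corr, summary = correlation_matrix(t, {"x": ("a", "b"), "y": ("c",)})
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert summary.loc["x", "x"] == pytest.approx(1.0)

    def test_independent_features_low_mean_abs_r(self, rng):
        t = pd.DataFrame(rng.normal(size=(10_000, 4)), columns=list("abcd"))
        _, summary = correlation_matrix(t, {"g1": ("a", "b"), "g2": ("c", "d")})
        assert summary.loc["g1", "g2"] < 0.03

    def test_coupled_harmonic_ratios_strongly_related(self, rng):
        # FHFBF and FHFn share FHF and the total-power denominator
        bf = rng.uniform(5, 10, 400)
        fhf = rng.uniform(1, 6, 400)
        shf = rng.uniform(0.2, 1.0, 400)
        t = pd.DataFrame({"FHFBF": fhf / bf, "FHFn": fhf / (bf + fhf + shf)})
        corr, _ = correlation_matrix(t, {"freq": ("FHFBF", "FHFn")})
        assert corr.loc["FHFBF", "FHFn"] > 0.5

    def test_too_few_rows_rejected(self):
        t = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(ValueError):
            correlation_matrix(t, {"f": ("a", "b")})
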