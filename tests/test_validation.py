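import itertools

import numpy as np
import pytest
from scipy import stats

from immunometa.errors import InsufficientDataError
from immunometa.features import FeatureMatrix
from immunometa.modules import ModuleSet
from immunometa.validation import (
    aggregate_module_auc,
    compare_groups,
    module_auc,
    module_scores,
    permutation_module_test,
    predict_response,
    severity_correlation,
    zscale_rows,
    AUCRecord,
    STABILITY_CAP,
)


def brute_force_auc(case, control):
    wins = sum(
        1.0 if c > k else (0.5 if c == k else 0.0)
        for c in case
        for k in control
    )
    return wins / (len(case) * len(control))


def feature_matrix(matrix, study_id="s1", prefix="f"):
    matrix = np.asarray(matrix, dtype=float)
    return FeatureMatrix(
        feature_ids=[f"{prefix}{i}" for i in range(matrix.shape[0])],
        feature_type="mixed",
        matrix=matrix,
        study_id=study_id,
        sample_ids=[f"{study_id}_x{j}" for j in range(matrix.shape[1])],
    )


class TestModuleScores:
    def test_singleton_module(self):
        fm = feature_matrix([[1.0, 2.0, 3.0, 4.0]])
        scores = module_scores(fm, ModuleSet(modules={1: ["f0"]}))
        np.testing.assert_allclose(scores.scores[0], zscale_rows(fm.matrix)[0])

    def test_constant_feature_contributes_zero(self):
        fm = feature_matrix([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]])
        scores = module_scores(fm, ModuleSet(modules={1: ["f0", "f1"]}))
        np.testing.assert_allclose(scores.scores[0], zscale_rows(fm.matrix)[1])

    def test_hand_computed_three_by_four(self):
        matrix = np.array(
            [[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0], [0.0, 1.0, 0.0, 1.0]]
        )
        fm = feature_matrix(matrix)
        scores = module_scores(fm, ModuleSet(modules={1: ["f0", "f1", "f2"]}))
        scaled = (matrix - matrix.mean(axis=1, keepdims=True)) / matrix.std(axis=1, keepdims=True)
        np.testing.assert_allclose(scores.scores[0], scaled.sum(axis=0), atol=1e-12)

    def test_missing_feature_module_scores_nan(self):
        fm = feature_matrix([[1.0, 2.0, 3.0]])
        scores = module_scores(fm, ModuleSet(modules={1: ["f0"], 2: ["ghost"]}))
        assert np.isnan(scores.scores[1]).all()
        assert scores.coverage == {1: 1, 2: 0}

    def test_sample_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        matrix = rng.normal(size=(5, 8))
        modules = ModuleSet(modules={1: ["f0", "f2"], 2: ["f1", "f3", "f4"]})
        base = module_scores(feature_matrix(matrix), modules)
        perm = rng.permutation(8)
        permuted = module_scores(feature_matrix(matrix[:, perm]), modules)
        np.testing.assert_allclose(permuted.scores, base.scores[:, perm], atol=1e-12)


class TestModuleAUC:
    def test_perfect_separation(self):
        scores = np.array([5.0, 6.0, 1.0, 2.0])
        rec = module_auc(scores, ["case", "case", "control", "control"])
        assert rec.auc == 1.0

    def test_all_ties(self):
        rec = module_auc(np.ones(6), ["case"] * 3 + ["control"] * 3)
        assert rec.auc == 0.5

    def test_pair_counting_example(self):
        rec = module_auc(np.array([3.0, 5.0, 1.0, 4.0]), ["case", "case", "control", "control"])
        assert rec.auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            module_auc(np.ones(3), ["case"] * 3)

    def test_brute_force_oracle_small_inputs(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 13))
            n_case = int(rng.integers(1, n))
            scores = rng.choice([0.0, 1.0, 2.5, 3.0, -1.0], size=n)  # ties likely
            labels = np.array(["case"] * n_case + ["control"] * (n - n_case))
            rec = module_auc(scores, labels)
            assert rec.auc == pytest.approx(
                brute_force_auc(scores[:n_case], scores[n_case:]), abs=1e-12
            )


class TestAggregateModuleAUC:
    def _records(self, aucs, ps=None):
        ps = ps or [0.5] * len(aucs)
        return [
            AUCRecord(module_id=1, study_id=f"s{i}", auc=a, p=p, n_case=10, n_control=10)
            for i, (a, p) in enumerate(zip(aucs, ps))
        ]

    def test_single_study_flagged(self):
        out = aggregate_module_auc(self._records([0.8]))
        assert out.mean_auc == 0.8
        assert out.stability_flagged

    def test_zero_variance_capped(self):
        out = aggregate_module_auc(self._records([0.7, 0.7, 0.7]))
        assert out.mean_auc == pytest.approx(0.7)
        assert out.stability == STABILITY_CAP
        assert out.stability_flagged

    def test_mean_sd_combined_p(self):
        out = aggregate_module_auc(self._records([0.6, 0.7, 0.8], ps=[0.01, 0.02, 0.5]))
        assert out.mean_auc == pytest.approx(0.7)
        assert out.sd_auc == pytest.approx(np.std([0.6, 0.7, 0.8], ddof=1))
        ref = stats.chi2.sf(-2 * np.sum(np.log([0.01, 0.02, 0.5])), df=6)
        assert out.combined_p == pytest.approx(ref)

    def test_mixed_modules_rejected(self):
        records = self._records([0.6, 0.7])
        records[1].module_id = 2
        with pytest.raises(ValueError):
            aggregate_module_auc(records)


def _planted_setup(rng, n_features=60, n_samples=40, shift=0.0, n_modules=6):
    matrix = rng.normal(size=(n_features, n_samples))
    labels = np.array(["case"] * (n_samples // 2) + ["control"] * (n_samples - n_samples // 2))
    per = n_features // n_modules
    modules = ModuleSet(
        modules={
            m + 1: [f"f{i}" for i in range(m * per, (m + 1) * per)] for m in range(n_modules)
        }
    )
    if shift:
        matrix[:per, labels == "case"] += shift
    return feature_matrix(matrix), modules, labels


class TestPermutationModuleTest:
    def test_deterministic(self, rng):
        fm, modules, labels = _planted_setup(rng)
        a = permutation_module_test(2, modules, fm, labels, n_perm=150, seed=4)
        b = permutation_module_test(2, modules, fm, labels, n_perm=150, seed=4)
        assert a == b

    def test_planted_module_highly_significant(self, rng):
        fm, modules, labels = _planted_setup(rng, shift=2.0)
        out = permutation_module_test(1, modules, fm, labels, n_perm=300, seed=5)
        assert out["p"] < 0.001
        assert out["effect"] > 0

    def test_insufficient_pool_rejected(self, rng):
        fm, _, labels = _planted_setup(rng, n_features=10)
        modules = ModuleSet(modules={1: [f"f{i}" for i in range(8)], 2: ["f8", "f9"]})
        with pytest.raises(ValueError, match="pool"):
            permutation_module_test(1, modules, fm, labels, n_perm=150, seed=0)

    def test_small_n_perm_rejected(self, rng):
        fm, modules, labels = _planted_setup(rng)
        with pytest.raises(ValueError):
            permutation_module_test(1, modules, fm, labels, n_perm=10)

    def test_empirical_p_reported(self, rng):
        fm, modules, labels = _planted_setup(rng)
        out = permutation_module_test(3, modules, fm, labels, n_perm=150, seed=6)
        assert 0.0 < out["p_empirical"] <= 1.0
        assert out["module_size"] == 10


class TestPredictResponse:
    def test_responders_below(self):
        rec = predict_response(
            np.array([1.0, 2.0, 8.0, 9.0]),
            ["responder", "responder", "non_responder", "non_responder"],
        )
        assert rec.auc == 1.0
        assert rec.direction == "lower_in_responders"

    def test_pair_counting(self):
        rec = predict_response(
            np.array([1.0, 2.0, 3.0, 4.0]),
            ["responder", "responder", "non_responder", "non_responder"],
        )
        assert rec.auc == 1.0  # raw AUC 0, directed 1
        assert rec.direction == "lower_in_responders"

    def test_null_mean_half(self, rng):
        aucs = []
        for _ in range(100):
            scores = rng.normal(size=20)
            labels = rng.permutation(["responder"] * 10 + ["non_responder"] * 10)
            rec = predict_response(scores, labels)
            raw = rec.auc if rec.direction == "higher_in_responders" else 1 - rec.auc
            aucs.append(raw)
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            predict_response(np.ones(3), ["responder"] * 3)


class TestSeverityCorrelation:
    def test_identity(self):
        scores = np.array([0.1, 0.4, 0.2, 0.9, 0.7])
        rho, p, n = severity_correlation(scores, scores)
        assert rho == pytest.approx(1.0)
        assert n == 5

    def test_antisymmetry(self):
        scores = np.array([0.1, 0.4, 0.2, 0.9, 0.7])
        rho, _, _ = severity_correlation(scores, -scores)
        assert rho == pytest.approx(-1.0)

    def test_missing_dropped_pairwise(self):
        scores = np.array([0.1, 0.4, 0.2, 0.9, 0.7, 0.3])
        severity = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 6.0])
        _, _, n = severity_correlation(scores, severity)
        assert n == 5

    def test_null_mean_near_zero(self, rng):
        rhos = [
            severity_correlation(rng.normal(size=40), rng.normal(size=40))[0]
            for _ in range(100)
        ]
        assert abs(np.mean(rhos)) < 0.1

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            severity_correlation(np.ones(3), np.arange(3.0))


class TestCompareGroups:
    def test_identical_groups(self):
        _, p = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p >= 0.99

    def test_disjoint_minimal_p(self):
        _, p = compare_groups([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        # exact two-sided rank-sum floor for n=3,3 is 2/C(6,3)
        assert p == pytest.approx(0.1)

    def test_monotone_invariance(self, rng):
        a, b = rng.normal(size=(2, 12))
        _, p1 = compare_groups(a, b)
        _, p2 = compare_groups(np.exp(a), np.exp(b))
        assert p1 == pytest.approx(p2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0])
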