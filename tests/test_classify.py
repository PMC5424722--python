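"""RBF kernel, pairwise SVMs, weighted voting and cross-validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermoseed import classify
from thermoseed.classify import (CLASS_ORDER, EnsembleModel, KernelSpec,
                                 accuracy_report, build_ensemble,
                                 cross_validate, kernel, kernel_matrix,
                                 predict, train_binary)


class TestKernel:
    def test_self_similarity_is_one(self):
        x = np.array([0.3, -1.2, 4.0])
        assert kernel(x, x) == pytest.approx(1.0)
        assert kernel(x, x, KernelSpec("unsquared", 2.0)) == pytest.approx(1.0)

    def test_hand_evaluated_value(self):
        # gamma=2, squared distance 1 -> e^-2
        x1 = np.array([0.0, 0.0])
        x2 = np.array([1.0, 0.0])
        assert kernel(x1, x2, KernelSpec(width=2.0)) == pytest.approx(
            np.exp(-2.0))

    def test_width_to_zero_limit_flattens(self):
        x1 = np.zeros(3)
        x2 = np.ones(3) * 5
        assert kernel(x1, x2, KernelSpec(width=1e-9)) == pytest.approx(1.0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            kernel(np.zeros(2), np.zeros(3))

    def test_matrix_symmetric_positive_semidefinite(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 4))
        K = kernel_matrix(X, X)
        assert np.allclose(K, K.T)
        assert np.all(np.linalg.eigvalsh(K) > -1e-10)
        assert np.all((K > 0) & (K <= 1.0 + 1e-12))


class TestTrainBinary:
    def test_two_point_problem(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        y = np.array(["viable", "aged"])
        model = train_binary(X, y, C=2.0)
        assert list(model.predict_pair(X)) == list(y)
        d = model.decision_value(X)
        assert d[0] * d[1] < 0

    def test_xor_pattern_separated_by_rbf(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array(["viable", "viable", "aged", "aged"])
        model = train_binary(X, y, C=2.0, spec=KernelSpec(width=2.0))
        assert list(model.predict_pair(X)) == list(y)

    def test_dual_constraints_hold_with_conflicting_duplicates(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [2.0, 0.0]])
        y = np.array(["viable", "aged", "aged"])
        model = train_binary(X, y, C=2.0)
        signed = model.dual_signed_alphas
        assert abs(signed.sum()) < 1e-9
        assert np.all(np.abs(signed) <= 2.0 + 1e-9)
        # the conflicted duplicate pins its multiplier at the C bound
        assert np.any(np.isclose(np.abs(signed), 2.0))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            train_binary(np.zeros((3, 2)), np.array(["viable"] * 3))

    @pytest.mark.parametrize("toy", [
        # separable and conflicting 2-D sets of <= 6 points
        ([[0, 0], [1, 0], [3, 3], [4, 3]], ["viable"] * 2 + ["aged"] * 2),
        ([[0, 0], [0, 1], [1, 0], [5, 5], [5, 6], [6, 5]],
         ["viable"] * 3 + ["aged"] * 3),
        ([[0, 0], [0, 0], [3, 0], [3, 1]], ["viable", "aged", "aged", "aged"]),
    ])
    def test_training_error_matches_brute_force_linear_search(self, toy):
        # oracle: exhaustive grid over (angle, offset) linear separators
        X = np.array(toy[0], dtype=float)
        y = np.array(toy[1])
        sign = np.where(y == "viable", 1.0, -1.0)
        best = len(y)
        for theta in np.linspace(0, np.pi, 181):
            w = np.array([np.cos(theta), np.sin(theta)])
            proj = X @ w
            for b in np.linspace(proj.min() - 1, proj.max() + 1, 400):
                for orient in (1.0, -1.0):
                    err = int(np.sum(orient * np.sign(proj - b) != sign))
                    best = min(best, err)
        model = train_binary(X, y, C=100.0, spec=KernelSpec(width=0.5))
        svm_err = int(np.sum(model.predict_pair(X) != y))
        assert svm_err == best


def toy_three_class(n_per=12, sep=4.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.concatenate([
        rng.normal([0.0, 0.0], 1.0, (n_per, 2)),
        rng.normal([sep, 0.0], 1.0, (n_per, 2)),
        rng.normal([0.0, sep], 1.0, (n_per, 2)),
    ])
    y = np.repeat(CLASS_ORDER, n_per)
    return X, y


class TestEnsemble:
    def test_equal_accuracies_give_uniform_weights(self):
        X, y = toy_three_class(sep=8.0)
        ens = build_ensemble(X, y)
        assert np.all(ens.training_accuracies == 1.0)
        assert np.allclose(ens.weights, 1 / 3)
        assert ens.weights.sum() == pytest.approx(1.0)

    def test_weight_normalization_arithmetic(self):
        # weights are p_i / sum(p); spot-check (1.0, 0.5, 0.5) -> (.5,.25,.25)
        p = np.array([1.0, 0.5, 0.5])
        w = p / p.sum()
        assert np.allclose(w, [0.5, 0.25, 0.25])

    @settings(max_examples=40, derandomize=True)
    @given(p=st.lists(st.floats(0.5, 1.0), min_size=3, max_size=3))
    def test_weights_always_normalized(self, p):
        # property: Eq-style normalization sums to 1 and preserves order
        p = np.array(p)
        w = p / p.sum()
        assert w.sum() == pytest.approx(1.0)
        assert np.all(w >= 0)
        assert np.array_equal(np.argsort(w), np.argsort(p))

    def test_missing_class_rejected(self):
        X = np.zeros((4, 2))
        y = np.array(["viable", "viable", "aged", "aged"])
        with pytest.raises(ValueError, match="lacks"):
            build_ensemble(X, y)

    def test_inner_cv_weights_less_optimistic_on_noise(self):
        # pure noise: resubstitution accuracies stay inflated, the inner
        # CV estimates hover near chance, and both still normalize to 1
        rng = np.random.default_rng(11)
        X = rng.normal(size=(60, 4))
        y = np.repeat(CLASS_ORDER, 20)
        resub = build_ensemble(X, y, p_mode="resubstitution")
        inner = build_ensemble(X, y, p_mode="inner_cv")
        assert inner.weights.sum() == pytest.approx(1.0)
        assert (inner.training_accuracies.mean()
                < resub.training_accuracies.mean())

    def test_unknown_p_mode_rejected(self):
        X, y = toy_three_class()
        with pytest.raises(ValueError, match="p_mode"):
            build_ensemble(X, y, p_mode="magic")

    def test_well_separated_cohort_trains_accurately(self, cohort_features):
        table, _, labels, _ = cohort_features
        from thermoseed.features import FEATURE_NAMES

        ens = build_ensemble(table[list(FEATURE_NAMES)].to_numpy(float),
                             labels)
        assert np.all(ens.training_accuracies >= 0.9)


class _Stub:
    """Fixed-vote binary stub standing in for a trained SVC."""

    def __init__(self, cls, margin):
        self.cls, self.margin = cls, margin

    def predict_pair(self, X):
        return np.array([self.cls] * len(np.atleast_2d(X)))

    def decision_value(self, X):
        return np.full(len(np.atleast_2d(X)), self.margin)


def stub_ensemble(votes, weights, margins=(1.0, 1.0, 1.0)):
    return EnsembleModel(
        models=[_Stub(v, m) for v, m in zip(votes, margins)],
        training_accuracies=np.asarray(weights, float),
        weights=np.asarray(weights, float), center=None, scale=None)


class TestPredictVoting:
    def test_two_votes_beat_one(self):
        ens = stub_ensemble(["viable", "viable", "aged"], [0.4, 0.3, 0.3])
        assert predict(ens, np.zeros((1, 2)))[0] == "viable"

    def test_three_way_split_takes_largest_weight(self):
        ens = stub_ensemble(["viable", "non_viable", "aged"],
                            [0.4, 0.35, 0.25])
        assert predict(ens, np.zeros((1, 2)))[0] == "viable"

    def test_weight_tie_broken_by_decision_magnitude(self):
        ens = stub_ensemble(["viable", "aged", "non_viable"],
                            [0.5, 0.5, 0.0], margins=(1.0, 2.0, 0.1))
        assert predict(ens, np.zeros((1, 2)))[0] == "aged"

    def test_full_tie_falls_back_to_class_order(self):
        ens = stub_ensemble(["aged", "non_viable", "viable"],
                            [0.5, 0.5, 0.0], margins=(1.0, 1.0, 9.9))
        # aged and non_viable tie on weight and margin; aged precedes? no:
        # viable < aged < non_viable, and viable has weight 0 -> aged wins
        assert predict(ens, np.zeros((1, 2)))[0] == "aged"

    def test_uniform_weights_equal_plain_majority(self):
        X, y = toy_three_class(sep=6.0, seed=3)
        weighted = build_ensemble(X, y, weighting="training_accuracy")
        uniform = build_ensemble(X, y, weighting="uniform")
        if np.all(weighted.training_accuracies
                  == weighted.training_accuracies[0]):
            assert np.array_equal(predict(weighted, X), predict(uniform, X))


class TestCrossValidate:
    def test_fold_sizes_on_120_cohort(self, cohort_features):
        table, _, labels, _ = cohort_features
        from thermoseed.features import FEATURE_NAMES

        rep = cross_validate(table[list(FEATURE_NAMES)].to_numpy(float),
                             labels, k=5, rng_seed=1)
        for fold in rep.folds:
            assert fold["train_n"] == 96
            assert fold["predict_n"] == 24
        assert rep.confusion.to_numpy().sum() == 120
        # confusion columns sum to the per-class prediction numbers
        col_sums = rep.confusion.sum(axis=0)
        assert col_sums["viable"] == 41
        assert col_sums["aged"] == 32
        assert col_sums["non_viable"] == 47

    def test_leave_one_out_on_toy(self):
        X, y = toy_three_class(n_per=2, sep=8.0)
        rep = cross_validate(X, y, k=6, rng_seed=0)
        assert all(f["predict_n"] == 1 for f in rep.folds)

    def test_same_seed_reproduces_report(self, cohort_features):
        _, early, labels, _ = cohort_features
        X = early.to_numpy(float)
        a = cross_validate(X, labels, k=5, rng_seed=5)
        b = cross_validate(X, labels, k=5, rng_seed=5)
        assert np.array_equal(a.fold_assignment, b.fold_assignment)
        assert np.array_equal(a.y_pred, b.y_pred)
        assert a.overall_accuracy == b.overall_accuracy

    def test_default_separation_recovers_labels(self, cohort_features):
        table, early, labels, _ = cohort_features
        from thermoseed.features import FEATURE_NAMES

        rep = cross_validate(table[list(FEATURE_NAMES)].to_numpy(float),
                             labels, k=5, rng_seed=0)
        assert rep.overall_accuracy >= 0.85
        rep_early = cross_validate(early.to_numpy(float), labels, k=5,
                                   rng_seed=0)
        assert rep_early.overall_accuracy >= 0.85

    def test_zero_separation_collapses_to_chance(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(90, 6))
        y = np.repeat(CLASS_ORDER, 30)
        rep = cross_validate(X, y, k=5, rng_seed=9)
        assert rep.overall_accuracy < 0.55  # near the 1/3 chance baseline


class TestAccuracyReport:
    def test_whole_data_published_counts(self):
        out = accuracy_report({"viable": 3, "aged": 3, "non_viable": 0},
                              {"viable": 41, "aged": 32, "non_viable": 47})
        assert out["overall"] == pytest.approx(0.95)
        assert out["viable"] == pytest.approx(38 / 41)
        assert out["aged"] == pytest.approx(29 / 32)
        assert out["non_viable"] == pytest.approx(1.0)

    def test_early_model_published_counts(self):
        out = accuracy_report({"viable": 1, "aged": 8, "non_viable": 1},
                              {"viable": 41, "aged": 32, "non_viable": 47})
        assert out["overall"] == pytest.approx(110 / 120)
        assert round(out["overall"] * 100, 2) == 91.67

    def test_perfect_counts(self):
        out = accuracy_report({"viable": 0, "aged": 0, "non_viable": 0},
                              {"viable": 10, "aged": 10, "non_viable": 10})
        assert all(v == 1.0 for v in out.values())

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            accuracy_report({"viable": 0}, {"viable": 0})
        with pytest.raises(ValueError, match="outside"):
            accuracy_report({"viable": 5}, {"viable": 4})
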