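"""SGD classifier, LOO evaluation, subset sweep, and ROC/AUC checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import scarmorph as sm
from scarmorph.classify import (SGDConfig, confusion, fit_fold, loo_evaluate,
                                roc_auc, subset_sweep)
from scarmorph.errors import ParameterError
from scarmorph.features import FEATURE_NAMES

from conftest import small_design, small_presets


def _table_from_arrays(X, y):
    """Wrap a plain (X, y) problem in the cohort-table layout."""
    labels = np.asarray(["normal", "scar", "adjacent"])[np.asarray(y)]
    data = {"class_label": labels}
    for j in range(X.shape[1]):
        data[FEATURE_NAMES[j]] = X[:, j]
    for name in FEATURE_NAMES[X.shape[1]:]:
        data[name] = np.zeros(len(X))
    return pd.DataFrame(data, index=[f"s{i}" for i in range(len(X))])


def _blobs(rng, n_per_class=10, gap=8.0, n_features=2):
    centers = np.array([[0.0, 0], [gap, 0], [0, gap]])[:, :n_features]
    X = np.vstack([rng.normal(c, 1.0, size=(n_per_class, n_features))
                   for c in centers])
    y = np.repeat([0, 1, 2], n_per_class)
    return X, y


class TestTrainSGD:
    def test_separable_blobs_reach_training_accuracy_one(self):
        rng = np.random.default_rng(0)
        X, y = _blobs(rng, gap=12.0)
        model = sm.train_sgd(X, y, SGDConfig(), seed=1)
        assert (model.predict(X) == y).mean() == 1.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        X, y = _blobs(rng, gap=3.0)
        w1 = sm.train_sgd(X, y, SGDConfig(), seed=5).named_steps["sgd"].coef_
        w2 = sm.train_sgd(X, y, SGDConfig(), seed=5).named_steps["sgd"].coef_
        np.testing.assert_array_equal(w1, w2)

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            sm.train_sgd(np.zeros((5, 2)), np.zeros(5))


class TestLooEvaluate:
    def test_runs_exactly_n_folds(self):
        rng = np.random.default_rng(2)
        X, y = _blobs(rng, n_per_class=4)
        table = _table_from_arrays(X, y)
        acc, scores = loo_evaluate(table, FEATURE_NAMES[:2], SGDConfig(), seed=0)
        assert len(scores) == len(table)
        assert set(scores.columns) >= {"predicted", "true"}
        assert 0.0 <= acc <= 1.0

    def test_twin_dataset_perfect_loo(self):
        """Every sample has an identical same-label twin, so each held-out
        sample is classified by a model that saw its twin."""
        rng = np.random.default_rng(3)
        X, y = _blobs(rng, n_per_class=5, gap=10.0)
        X = np.vstack([X, X])
        y = np.concatenate([y, y])
        table = _table_from_arrays(X, y)
        acc, _ = loo_evaluate(table, FEATURE_NAMES[:2], SGDConfig(), seed=4)
        assert acc == 1.0

    def test_shuffled_labels_stay_at_chance(self):
        """Label-permuted LOO accuracy stays inside the chance band."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(60, 4))
            y = rng.permutation(np.repeat([0, 1, 2], 20))
            table = _table_from_arrays(X, y)
            acc, _ = loo_evaluate(table, FEATURE_NAMES[:4], SGDConfig(),
                                  seed=seed)
            assert 0.13 <= acc <= 0.55

    def test_no_leakage_from_held_out_sample(self):
        """Fold weights are identical no matter what the test sample holds."""
        rng = np.random.default_rng(5)
        X, y = _blobs(rng, n_per_class=4)
        table = _table_from_arrays(X, y)
        perturbed = table.copy()
        perturbed.iloc[0, 1:] = 1e6
        w_a = fit_fold(table, FEATURE_NAMES[:2], SGDConfig(), 0,
                       seed=9).named_steps["sgd"].coef_
        w_b = fit_fold(perturbed, FEATURE_NAMES[:2], SGDConfig(), 0,
                       seed=9).named_steps["sgd"].coef_
        np.testing.assert_array_equal(w_a, w_b)

    def test_unknown_feature_rejected(self):
        rng = np.random.default_rng(6)
        X, y = _blobs(rng, n_per_class=3)
        table = _table_from_arrays(X, y)
        with pytest.raises(ParameterError):
            loo_evaluate(table, ["C-density", "Q-bogus"], SGDConfig())


class TestSubsetSweep:
    def test_one_evaluation_per_subset(self):
        rng = np.random.default_rng(7)
        X, y = _blobs(rng, n_per_class=4, n_features=2)
        table = _table_from_arrays(X, y)
        subsets = [FEATURE_NAMES[:1], FEATURE_NAMES[:2], FEATURE_NAMES[:3]]
        evals, best_n = subset_sweep(table, subsets, SGDConfig(), repeats=2,
                                     base_seed=0)
        assert [e.subset_size for e in evals] == [1, 2, 3]
        assert all(len(e.accuracies) == 2 for e in evals)
        assert best_n in (1, 2, 3)

    def test_single_subset_best_n_is_its_size(self):
        rng = np.random.default_rng(8)
        X, y = _blobs(rng, n_per_class=4)
        table = _table_from_arrays(X, y)
        _, best_n = subset_sweep(table, [FEATURE_NAMES[:2]], SGDConfig(),
                                 repeats=1, base_seed=0)
        assert best_n == 2

    def test_deterministic_given_base_seed(self):
        rng = np.random.default_rng(9)
        X, y = _blobs(rng, n_per_class=4, gap=2.0)
        table = _table_from_arrays(X, y)
        subsets = [FEATURE_NAMES[:2]]
        a, _ = subset_sweep(table, subsets, SGDConfig(), repeats=3, base_seed=5)
        b, _ = subset_sweep(table, subsets, SGDConfig(), repeats=3, base_seed=5)
        assert a == b

    def test_ties_break_toward_smaller_subset(self):
        """With duplicated feature columns the accuracies tie; parsimony wins."""
        rng = np.random.default_rng(10)
        X, y = _blobs(rng, n_per_class=5, gap=12.0)
        X = np.column_stack([X, X])  # features 3,4 duplicate 1,2
        table = _table_from_arrays(X, y)
        _, best_n = subset_sweep(
            table, [FEATURE_NAMES[:2], FEATURE_NAMES[:4]], SGDConfig(),
            repeats=1, base_seed=0)
        assert best_n == 2


class TestRocAuc:
    @staticmethod
    def _frame(score, truth, cls="scar"):
        other = "normal"
        frame = pd.DataFrame({f"proba_{cls}": score})
        frame["true"] = np.where(truth, cls, other)
        frame["predicted"] = frame["true"]
        return frame

    def test_perfect_separation_auc_one(self):
        frame = self._frame(np.array([0.9, 0.8, 0.2, 0.1]),
                            np.array([1, 1, 0, 0]))
        assert roc_auc(frame)["scar"]["auc"] == 1.0

    def test_random_scores_mean_auc_half(self):
        aucs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            frame = self._frame(rng.uniform(size=30),
                                rng.integers(0, 2, size=30).astype(bool)
                                | np.array([True] + [False] * 29))
            aucs.append(roc_auc(frame)["scar"]["auc"])
        assert abs(np.mean(aucs) - 0.5) < 0.1

    @pytest.mark.parametrize("seed", range(100))
    def test_trapezoid_auc_equals_mann_whitney_u(self, seed):
        """AUC by trapezoidal ROC integration equals U/(n_pos*n_neg)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 40))
        truth = np.zeros(n, dtype=bool)
        truth[:int(rng.integers(1, n))] = True
        # coarse grid forces ties, exercising the rank-equivalence
        score = rng.integers(0, 5, size=n) / 4.0
        frame = self._frame(score, truth)
        auc = roc_auc(frame)["scar"]["auc"]
        pos, neg = score[truth], score[~truth]
        u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
        assert auc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-12)

    def test_absent_class_rejected(self):
        frame = self._frame(np.array([0.5, 0.6]), np.array([True, True]))
        frame["true"] = "normal"
        with pytest.raises(ParameterError):
            roc_auc(frame)

    def test_confusion_matrix_conserves_sample_count(self):
        rng = np.random.default_rng(11)
        X, y = _blobs(rng, n_per_class=4, gap=2.0)
        table = _table_from_arrays(X, y)
        _, scores = loo_evaluate(table, FEATURE_NAMES[:2], SGDConfig(), seed=0)
        mat, classes = confusion(scores)
        assert mat.sum() == len(table)
        counts = scores["true"].value_counts()
        for i, cls in enumerate(classes):
            assert mat[i].sum() == counts[cls]


class TestSeparationMonotonicity:
    def test_widening_class_gaps_does_not_hurt_accuracy(self):
        """Mean LOO accuracy is non-decreasing over 3 simulator gap levels
        (1 violation allowed across the 5-seed means)."""
        from scarmorph.features import build_cohort_table
        import dataclasses

        def blended(alpha):
            # alpha=0: all classes collapse onto the normal preset;
            # alpha=1: full default contrast
            presets = small_presets()
            ref = presets["normal"]
            out = {}
            for label, per_ch in presets.items():
                out[label] = {}
                for ch, p in per_ch.items():
                    r = ref[ch]
                    mix = {f: (1 - alpha) * getattr(r, f) + alpha * getattr(p, f)
                           for f in ("length_mean", "length_sd", "width_mean",
                                     "dispersion_k", "intensity_mean",
                                     "intensity_sd", "noise_sd")}
                    mix["n_fibers"] = int(round((1 - alpha) * r.n_fibers
                                                + alpha * p.n_fibers))
                    out[label][ch] = dataclasses.replace(p, **mix)
            return out

        means = []
        for alpha in (0.25, 0.6, 1.0):
            accs = []
            for seed in range(5):
                design = small_design(master_seed=50 + seed,
                                      class_params=blended(alpha))
                table = build_cohort_table(sm.generate_cohort(design))
                acc, _ = loo_evaluate(table, FEATURE_NAMES, SGDConfig(),
                                      seed=seed)
                accs.append(acc)
            means.append(np.mean(accs))
        violations = sum(b < a - 1e-9 for a, b in zip(means, means[1:]))
        assert violations <= 1, means
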