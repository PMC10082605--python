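"""SGD classifier training, leave-one-out evaluation, subset sweep, ROC/AUC.

The classifier is the linear model found by AutoML model selection in the
source workflow: a one-vs-rest stochastic-gradient-descent classifier with
modified-Huber loss and elastic-net penalty (alpha 0.001, constant learning
rate eta0 0.01).  Because SGD with a constant learning rate is
scale-sensitive, features are z-scored inside each training fold — the
held-out sample never touches the standardization statistics.  Evaluation is
leave-one-out (LOO): with a few dozen samples it is both the least biased
and fully deterministic given the model seed.  Held-out modified-Huber
probability scores feed one-vs-rest ROC curves with trapezoidal AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import SGDClassifier
from sklearn.metrics import auc as trapezoid_auc
from sklearn.metrics import confusion_matrix as sk_confusion
from sklearn.metrics import roc_curve
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .errors import ParameterError
from .features import LABEL_COLUMN, validate_cohort_table

SCORE_PREFIX = "proba_"


@dataclass(frozen=True)
class SGDConfig:
    """Hyperparameters of the final linear model.

    ``power_t`` only matters for an inverse-scaling learning-rate schedule;
    it is inert under the constant schedule used here but kept as part of
    the model description.  ``l1_ratio`` balances the elastic-net mix
    (0 = ridge, 1 = lasso).
    """

    loss: str = "modified_huber"
    penalty: str = "elasticnet"
    alpha: float = 0.001
    eta0: float = 0.01
    learning_rate: str = "constant"
    fit_intercept: bool = True
    power_t: float = 0.5
    l1_ratio: float = 0.15
    max_epochs: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.eta0 <= 0:
            raise ParameterError("alpha and eta0 must be positive")
        if not 0.0 <= self.l1_ratio <= 1.0:
            raise ParameterError("l1_ratio must lie in [0, 1]")

    def build(self, seed: int | None = None) -> Pipeline:
        """A fold-safe estimator: per-fold z-scoring + the SGD model."""
        return Pipeline([
            ("scale", StandardScaler()),
            ("sgd", SGDClassifier(
                loss=self.loss, penalty=self.penalty, alpha=self.alpha,
                l1_ratio=self.l1_ratio, eta0=self.eta0,
                learning_rate=self.learning_rate,
                fit_intercept=self.fit_intercept, power_t=self.power_t,
                max_iter=self.max_epochs,
                random_state=self.seed if seed is None else int(seed))),
        ])


def train_sgd(features: np.ndarray, labels: np.ndarray,
              config: SGDConfig | None = None,
              seed: int | None = None) -> Pipeline:
    """Fit the standardize+SGD pipeline on a full training set."""
    config = config or SGDConfig()
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ParameterError("training needs at least 2 classes")
    model = config.build(seed=seed)
    model.fit(np.asarray(features, dtype=float), labels)
    return model


def _proba_in_class_order(model: Pipeline, X: np.ndarray,
                          classes: np.ndarray) -> np.ndarray:
    """predict_proba mapped onto a fixed global class order."""
    raw = model.predict_proba(X)
    out = np.zeros((X.shape[0], len(classes)))
    for k, cls in enumerate(model.named_steps["sgd"].classes_):
        out[:, list(classes).index(cls)] = raw[:, k]
    return out


def _subset_matrix(table: pd.DataFrame, feature_subset) -> np.ndarray:
    unknown = [f for f in feature_subset if f not in table.columns]
    if unknown:
        raise ParameterError(f"unknown features in subset: {unknown}")
    return table[list(feature_subset)].to_numpy(dtype=float)


def fit_fold(table: pd.DataFrame, feature_subset, config: SGDConfig,
             test_index: int, seed: int | None = None) -> Pipeline:
    """Train the model for the LOO fold that holds out sample ``test_index``.

    Exposed so the no-leakage property (fold weights independent of the
    held-out sample) is directly checkable.
    """
    X = _subset_matrix(table, feature_subset)
    y = table[LABEL_COLUMN].to_numpy()
    train = np.arange(len(table)) != test_index
    return train_sgd(X[train], y[train], config, seed=seed)


def loo_evaluate(table: pd.DataFrame, feature_subset,
                 config: SGDConfig | None = None,
                 seed: int | None = None) -> tuple[float, pd.DataFrame]:
    """Leave-one-out evaluation of one feature subset.

    Runs exactly n folds; standardization and training see only the n-1
    training samples of each fold.  Returns the LOO accuracy and a
    per-sample frame with held-out class probabilities, prediction and
    truth (for ROC analysis).
    """
    config = config or SGDConfig()
    validate_cohort_table(table)
    y = table[LABEL_COLUMN].to_numpy()
    classes = np.unique(y)
    n = len(table)
    if n < len(classes) + 1:
        raise ParameterError(
            f"LOO needs at least n_classes+1 samples, got {n}")
    X = _subset_matrix(table, feature_subset)

    proba = np.zeros((n, len(classes)))
    predicted = np.empty(n, dtype=object)
    for i in range(n):
        train = np.arange(n) != i
        model = train_sgd(X[train], y[train], config, seed=seed)
        proba[i] = _proba_in_class_order(model, X[i:i + 1], classes)[0]
        predicted[i] = model.predict(X[i:i + 1])[0]
    accuracy = float(np.mean(predicted == y))
    scores = pd.DataFrame(
        proba, index=table.index,
        columns=[f"{SCORE_PREFIX}{c}" for c in classes])
    scores["predicted"] = predicted
    scores["true"] = y
    return accuracy, scores


@dataclass(frozen=True)
class SubsetEvaluation:
    subset_size: int
    accuracies: tuple[float, ...]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))


def subset_sweep(table: pd.DataFrame, subsets, config: SGDConfig | None = None,
                 repeats: int = 5, base_seed: int = 0,
                 ) -> tuple[list[SubsetEvaluation], int]:
    """Repeat-averaged LOO accuracy for each nested subset.

    Each (subset, repeat) pair gets its own derived model seed; ``best_n``
    is the smallest subset size attaining the maximum mean accuracy
    (parsimony tie-break).
    """
    if not subsets:
        raise ParameterError("subset list must be nonempty")
    config = config or SGDConfig()
    evaluations = []
    for subset in subsets:
        n = len(subset)
        accs = []
        for r in range(repeats):
            seed = int(np.random.SeedSequence([base_seed, n, r])
                       .generate_state(1)[0] >> 1)
            acc, _ = loo_evaluate(table, subset, config, seed=seed)
            accs.append(acc)
        evaluations.append(SubsetEvaluation(subset_size=n,
                                            accuracies=tuple(accs)))
    means = np.array([e.mean_accuracy for e in evaluations])
    sizes = np.array([e.subset_size for e in evaluations])
    at_max = sizes[means >= means.max() - 1e-12]
    best_n = int(at_max.min())
    return evaluations, best_n


def roc_auc(scores: pd.DataFrame) -> dict[str, dict]:
    """One-vs-rest ROC curves and trapezoidal AUC from held-out scores.

    For each class the positive score is that class's held-out probability;
    tied scores collapse into one ROC step, so the trapezoidal area equals
    the rank-based (Mann-Whitney) AUC.
    """
    score_cols = [c for c in scores.columns if c.startswith(SCORE_PREFIX)]
    if not score_cols or "true" not in scores.columns:
        raise ParameterError("scores frame must hold proba_* and true columns")
    truths = scores["true"].to_numpy()
    out = {}
    for col in score_cols:
        cls = col[len(SCORE_PREFIX):]
        if cls not in truths:
            raise ParameterError(f"class {cls!r} absent from labels")
        y_bin = (truths == cls).astype(int)
        fpr, tpr, thresholds = roc_curve(y_bin, scores[col].to_numpy())
        out[cls] = {"fpr": fpr, "tpr": tpr, "thresholds": thresholds,
                    "auc": float(trapezoid_auc(fpr, tpr))}
    return out


def confusion(scores: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Confusion matrix (rows = true class) from a LOO score frame."""
    classes = sorted(np.unique(scores["true"]))
    mat = sk_confusion(scores["true"], scores["predicted"], labels=classes)
    return mat, classes


def evaluations_to_frame(evaluations: list[SubsetEvaluation]) -> pd.DataFrame:
    rows = [(e.subset_size, r, acc)
            for e in evaluations for r, acc in enumerate(e.accuracies)]
    return pd.DataFrame(rows, columns=["n", "repeat", "accuracy"])
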