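"""Minimum-redundancy maximum-relevance (MRMR) feature ranking.

Relevance is the mutual information I(x_j; c) between a feature and the
class label; redundancy is the mean mutual information between a candidate
and the already-selected features.  Features are ranked greedily: the first
maximizes relevance, and the m-th maximizes

    I(x_j; c) - (1/(m-1)) * sum_{x_i in S_{m-1}} I(x_j; x_i)

(the additive "MID" criterion).  With a few dozen samples, continuous MI is
estimated by the plug-in estimator on equal-frequency (quantile) bins.  Ties
break toward the canonical feature order, so rankings are reproducible.

`MRMRRanker` is a scikit-learn compatible estimator (fit/transform,
get_params/set_params) so the ranking can sit inside sklearn pipelines and
model selection; `mrmr_rank` and `incremental_subsets` are thin functional
wrappers used by the pipeline driver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .errors import ParameterError
from .features import LABEL_COLUMN

DEFAULT_BINS = 4


def quantile_discretize(values: np.ndarray, bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Cut one continuous feature into at most ``bins`` equal-frequency bins.

    Duplicate quantile edges (heavy ties) are merged; a constant feature
    collapses to a single bin, which carries zero information with anything.
    Returns (integer codes, bin edges).
    """
    if bins < 2:
        raise ParameterError("bins must be >= 2")
    x = pd.Series(np.asarray(values, dtype=float))
    try:
        codes, edges = pd.qcut(x, q=bins, labels=False, retbins=True,
                               duplicates="drop")
    except ValueError:  # constant feature: all edges identical
        return np.zeros(len(x), dtype=int), np.array([x.iloc[0], x.iloc[0]])
    codes = codes.to_numpy()
    if np.any(pd.isna(codes)):  # degenerate: a single surviving bin
        codes = np.zeros(len(x))
    return codes.astype(int), edges


@dataclass(frozen=True)
class DiscretizedTable:
    codes: np.ndarray            # (n_samples, n_features) integer bin codes
    edges: list[np.ndarray]      # per-feature bin edges
    target: np.ndarray           # (n_samples,) integer class codes
    feature_names: list[str]


def discretize(table: pd.DataFrame, bins: int = DEFAULT_BINS) -> DiscretizedTable:
    """Discretize a feature table (label column + feature columns) for MI.

    Any column besides ``class_label`` is treated as a continuous feature;
    the canonical 28-column cohort table is the usual input, but smaller
    tables work the same way.
    """
    if LABEL_COLUMN not in table.columns:
        raise ParameterError(f"table is missing the {LABEL_COLUMN!r} column")
    names = [c for c in table.columns if c != LABEL_COLUMN]
    if not names:
        raise ParameterError("table has no feature columns")
    values = table[names].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        bad = table.index[~np.isfinite(values).all(axis=1)].tolist()
        raise ParameterError(f"non-finite feature values for samples {bad}")
    codes = np.empty((len(table), len(names)), dtype=int)
    edges = []
    for j, name in enumerate(names):
        c, e = quantile_discretize(values[:, j], bins)
        codes[:, j] = c
        edges.append(e)
    target = pd.Categorical(table[LABEL_COLUMN]).codes.astype(int)
    return DiscretizedTable(codes=codes, edges=edges, target=target,
                            feature_names=names)


def mutual_information(x_codes: np.ndarray, y_codes: np.ndarray) -> float:
    """Plug-in mutual information, in bits, between two code vectors.

    I = sum over occupied joint cells of p(a,b) log2[p(a,b)/(p(a)p(b))],
    clamped at 0 against rounding.
    """
    x = np.asarray(x_codes).ravel()
    y = np.asarray(y_codes).ravel()
    if x.shape != y.shape or x.size == 0:
        raise ParameterError("code vectors must have equal nonzero length")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx, ny = xi.max() + 1, yi.max() + 1
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny) / x.size
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nzr, nzc = joint.nonzero()
    pj = joint[nzr, nzc]
    terms = pj * np.log2(pj / (px[nzr] * py[nzc]))
    # summing in sorted order makes I(x;y) == I(y;x) bit-exact
    mi = float(np.sum(np.sort(terms)))
    return max(mi, 0.0)


#: Greedy scores closer than this are treated as tied (and break toward the
#: canonical feature order).  Distinct columns often share a joint-histogram
#: shape on small discretized tables, producing mathematically equal scores
#: that differ only in summation rounding.
TIE_TOL = 1e-12


def _greedy_rank(codes: np.ndarray, target: np.ndarray):
    """Greedy MID ranking over feature columns; returns (order, scores, relevance)."""
    n_features = codes.shape[1]
    if len(np.unique(target)) < 2:
        raise ParameterError("MRMR needs a target with at least 2 classes")
    relevance = np.array([mutual_information(codes[:, j], target)
                          for j in range(n_features)])
    pair_mi = np.full((n_features, n_features), np.nan)

    def pair(a: int, b: int) -> float:
        if np.isnan(pair_mi[a, b]):
            pair_mi[a, b] = pair_mi[b, a] = mutual_information(
                codes[:, a], codes[:, b])
        return pair_mi[a, b]

    order: list[int] = []
    scores: list[float] = []
    remaining = list(range(n_features))
    while remaining:
        best_j, best_score = None, None
        for j in remaining:
            redundancy = (np.mean([pair(j, i) for i in order])
                          if order else 0.0)
            score = relevance[j] - redundancy
            if best_score is None or score > best_score + TIE_TOL:
                best_j, best_score = j, score
        order.append(best_j)
        scores.append(float(best_score))
        remaining.remove(best_j)
    return order, scores, relevance


@dataclass(frozen=True)
class RankingResult:
    ranked_features: list[str]
    criterion_values: list[float]
    relevance: dict[str, float]

    def __post_init__(self) -> None:
        if sorted(self.ranked_features) != sorted(set(self.ranked_features)):
            raise ParameterError("ranking must be a permutation without repeats")


class MRMRRanker(BaseEstimator, TransformerMixin):
    """MRMR feature ranking as a scikit-learn transformer.

    Parameters
    ----------
    n_bins : int, default 4
        Equal-frequency bins used by the plug-in MI estimator.
    n_select : int or None, default None
        How many top-ranked features ``transform`` keeps (None keeps all,
        reordered by rank).

    Attributes
    ----------
    ranking_ : ndarray of column indices, best first.
    relevance_ : ndarray, I(x_j; c) in bits per input column.
    criterion_values_ : ndarray, greedy objective value at each step.
    """

    def __init__(self, n_bins: int = DEFAULT_BINS, n_select: int | None = None):
        self.n_bins = n_bins
        self.n_select = n_select

    def fit(self, X, y):
        if hasattr(X, "columns"):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        X = check_array(X, dtype=float, ensure_min_features=1)
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ParameterError("X and y have inconsistent lengths")
        codes = np.empty_like(X, dtype=int)
        for j in range(X.shape[1]):
            codes[:, j], _ = quantile_discretize(X[:, j], self.n_bins)
        target = np.unique(y, return_inverse=True)[1]
        order, scores, relevance = _greedy_rank(codes, target)
        self.n_features_in_ = X.shape[1]
        self.ranking_ = np.asarray(order)
        self.criterion_values_ = np.asarray(scores)
        self.relevance_ = relevance
        return self

    def transform(self, X):
        check_is_fitted(self, "ranking_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ParameterError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}")
        k = self.n_select if self.n_select is not None else self.n_features_in_
        return X[:, self.ranking_[:k]]


def mrmr_rank(dtable: DiscretizedTable) -> RankingResult:
    """Rank a discretized cohort table; ties break by canonical order."""
    order, scores, relevance = _greedy_rank(dtable.codes, dtable.target)
    names = dtable.feature_names
    return RankingResult(
        ranked_features=[names[j] for j in order],
        criterion_values=scores,
        relevance={names[j]: float(relevance[j]) for j in range(len(names))})


def incremental_subsets(ranking: RankingResult) -> list[list[str]]:
    """Nested subsets S_1 ⊂ S_2 ⊂ ... from a ranking (n-th holds top n)."""
    return [ranking.ranked_features[:n]
            for n in range(1, len(ranking.ranked_features) + 1)]


def write_ranking(ranking: RankingResult, path) -> None:
    df = pd.DataFrame({
        "rank": np.arange(1, len(ranking.ranked_features) + 1),
        "feature": ranking.ranked_features,
        "criterion_value": ranking.criterion_values,
        "relevance_bits": [ranking.relevance[f] for f in ranking.ranked_features],
    })
    df.to_csv(path, index=False, float_format="%.12g")


def read_ranking(path) -> RankingResult:
    df = pd.read_csv(path)
    required = {"rank", "feature", "criterion_value", "relevance_bits"}
    if not required <= set(df.columns):
        raise ParameterError(f"ranking file must have columns {sorted(required)}")
    df = df.sort_values("rank")
    return RankingResult(
        ranked_features=df["feature"].tolist(),
        criterion_values=df["criterion_value"].tolist(),
        relevance=dict(zip(df["feature"], df["relevance_bits"])))
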