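"""Preprocessing: quantile normalization and mixed-type imputation.

Both steps are scikit-learn transformers so they compose into pipelines,
plus thin functional wrappers operating on :class:`TabularDataset`.

Quantile normalization equalizes the distributions of the numeric
columns: each column is ranked, the reference distribution is the mean
of the rank-sorted columns, and every value is replaced by the reference
value at its within-column rank.  Missing entries are ignored when
ranking and carried through untouched, so imputation can follow.
Imputation substitutes the column mean for missing numeric entries and
the modal category for missing categorical entries.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .data import CATEGORICAL, NUMERIC, TabularDataset

__all__ = ["QuantileNormalizer", "MixedTypeImputer", "quantile_normalize", "impute_missing"]


def _check_matrix(X) -> np.ndarray:
    return check_array(X, dtype=float, ensure_all_finite="allow-nan", ensure_min_samples=2)


class QuantileNormalizer(BaseEstimator, TransformerMixin):
    """Force the numeric columns to share one reference distribution.

    Parameters
    ----------
    numeric_features : sequence of column indices to normalize; ``None``
        means every column.

    The reference is learned from the fitted (training) matrix: the mean
    of the per-column quantile functions on a grid of ``k`` evenly spaced
    probabilities, which for complete columns is exactly the row-wise
    mean of the sorted columns.  ``fit_transform`` assigns training
    values by exact within-column rank, averaging the reference over tied
    blocks so ties stay deterministic; ``transform`` maps unseen values
    onto the reference by interpolated rank against the training column.
    Missing (NaN) entries pass through unchanged.
    """

    def __init__(self, numeric_features=None):
        self.numeric_features = numeric_features

    def _columns(self, n: int) -> np.ndarray:
        if self.numeric_features is None:
            return np.arange(n)
        cols = np.asarray(self.numeric_features, dtype=int)
        if cols.size and (cols.min() < 0 or cols.max() >= n):
            raise ValueError("numeric_features index out of range")
        return cols

    def fit(self, X, y=None):
        X = _check_matrix(X)
        k = X.shape[0]
        cols = self._columns(X.shape[1])
        if cols.size == 0:
            raise ValueError("nothing to normalize: no numeric columns")
        grid = np.linspace(0.0, 1.0, k)
        quantiles = np.zeros((k, 0))
        sorted_obs: dict[int, np.ndarray] = {}
        per_col = []
        for j in cols:
            obs = np.sort(X[~np.isnan(X[:, j]), j])
            sorted_obs[int(j)] = obs
            if obs.size == 0:
                continue  # all-missing column contributes nothing
            if obs.size == 1:
                per_col.append(np.full(k, obs[0]))
            else:
                per_col.append(np.interp(grid, np.linspace(0.0, 1.0, obs.size), obs))
        if not per_col:
            raise ValueError("nothing to normalize: every candidate column is all-missing")
        self.reference_ = np.mean(per_col, axis=0)
        self.columns_ = cols
        self.sorted_obs_ = sorted_obs
        self.n_features_in_ = X.shape[1]
        return self

    def _map_column_exact(self, col: np.ndarray) -> np.ndarray:
        """In-sample rank assignment with tie blocks averaged."""
        ref = self.reference_
        k = ref.size
        out = col.copy()
        observed = ~np.isnan(col)
        m = int(observed.sum())
        if m == 0:
            return out
        vals = col[observed]
        order = np.argsort(vals, kind="stable")
        # reference value for each rank position of this column
        if m == 1:
            ranked_ref = np.array([np.interp(0.5 * (k - 1), np.arange(k), ref)])
        elif m == k:
            ranked_ref = ref
        else:
            pos = np.linspace(0.0, 1.0, m) * (k - 1)
            ranked_ref = np.interp(pos, np.arange(k), ref)
        mapped = np.empty(m)
        sorted_vals = vals[order]
        start = 0
        while start < m:  # average reference over each tied block
            stop = start
            while stop < m and sorted_vals[stop] == sorted_vals[start]:
                stop += 1
            mapped[order[start:stop]] = ranked_ref[start:stop].mean()
            start = stop
        out[observed] = mapped
        return out

    def transform(self, X):
        check_is_fitted(self, "reference_")
        X = _check_matrix(X).copy()
        if X.shape[1] != self.n_features_in_:
            raise ValueError("column count differs from the fitted matrix")
        ref = self.reference_
        k = ref.size
        for j in self.columns_:
            obs = self.sorted_obs_[int(j)]
            if obs.size == 0:
                continue
            col = X[:, j]
            observed = ~np.isnan(col)
            if obs.size == 1:
                X[observed, j] = np.interp(0.5 * (k - 1), np.arange(k), ref)
                continue
            p = np.interp(col[observed], obs, np.linspace(0.0, 1.0, obs.size))
            X[observed, j] = np.interp(p * (k - 1), np.arange(k), ref)
        return X

    def fit_transform(self, X, y=None, **fit_params):
        self.fit(X, y)
        X = _check_matrix(X).copy()
        for j in self.columns_:
            X[:, j] = self._map_column_exact(X[:, j])
        return X


class MixedTypeImputer(BaseEstimator, TransformerMixin):
    """Mean substitution for numeric columns, mode for categorical ones.

    ``categorical_features`` lists the categorical column indices;
    everything else is treated as numeric.  Modal ties break toward the
    smallest category code.  A column with no observed value in ``fit``
    raises, naming the column.
    """

    def __init__(self, categorical_features=()):
        self.categorical_features = categorical_features

    def fit(self, X, y=None):
        X = _check_matrix(X)
        n = X.shape[1]
        categorical = np.zeros(n, dtype=bool)
        categorical[np.asarray(list(self.categorical_features), dtype=int)] = True
        fill = np.empty(n)
        for j in range(n):
            obs = X[~np.isnan(X[:, j]), j]
            if obs.size == 0:
                raise ValueError(f"column {j} is fully missing; cannot impute")
            if categorical[j]:
                levels, counts = np.unique(obs, return_counts=True)
                fill[j] = levels[np.argmax(counts)]  # ties: lowest code wins
            else:
                fill[j] = obs.mean()
        self.statistics_ = fill
        self.categorical_mask_ = categorical
        self.n_features_in_ = n
        return self

    def transform(self, X):
        check_is_fitted(self, "statistics_")
        X = _check_matrix(X).copy()
        if X.shape[1] != self.n_features_in_:
            raise ValueError("column count differs from the fitted matrix")
        missing = np.isnan(X)
        for j in range(X.shape[1]):
            X[missing[:, j], j] = self.statistics_[j]
        return X


# -- TabularDataset wrappers ---------------------------------------------

def quantile_normalize(data: TabularDataset) -> TabularDataset:
    """Quantile-normalize the numeric columns of a dataset (in-sample)."""
    cols = data.numeric_columns
    if cols.size == 0:
        raise ValueError("nothing to normalize: dataset has no numeric columns")
    qn = QuantileNormalizer(numeric_features=cols)
    return data.with_values(qn.fit_transform(data.values))


def impute_missing(data: TabularDataset) -> TabularDataset:
    """Fill every missing entry by column mean (numeric) or mode (categorical)."""
    imp = MixedTypeImputer(categorical_features=data.categorical_columns)
    out = data.with_values(imp.fit_transform(data.values))
    named_check = np.isnan(out.values)
    assert not named_check.any()
    return out
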