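"""Two-stage similarity-cascade feature selection.

Stage 1 scores every candidate column against the binary target with the
congruence coefficient (Tucker's uncentered correlation) and keeps the
top ``o``.  Stage 2 re-scores the survivors with the Kumar-Hassebrook
(continuous Tanimoto) similarity and keeps the top ``z``.  Both stages
compare feature columns with the label vector; ties break toward the
lower column index so selection is deterministic.
"""

from __future__ import annotations

import math

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_X_y, check_is_fitted

from .data import TabularDataset

__all__ = [
    "congruence_score",
    "khs_score",
    "select_top",
    "CongruenceKHSSelector",
    "cascade_select",
]


def _check_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    if a.size < 2:
        raise ValueError("vectors must have length >= 2")
    return a, b


def congruence_score(candidate, target, form: str = "tucker") -> float:
    """Congruence coefficient between two vectors, in [-1, 1].

    ``form="tucker"`` (default) is the standard definition
    ΣPR / sqrt(ΣP²·ΣR²).  ``form="unscaled"`` drops the square root
    (ΣPR / (ΣP²·ΣR²)), a non-scale-invariant variant retained for
    fidelity experiments.
    """
    p, r = _check_pair(candidate, target)
    pp = float(p @ p)
    rr = float(r @ r)
    if pp == 0.0 or rr == 0.0:
        raise ValueError("undefined congruence: zero-norm vector")
    num = float(p @ r)
    if form == "tucker":
        return num / math.sqrt(pp * rr)
    if form == "unscaled":
        return num / (pp * rr)
    raise ValueError(f"unknown form {form!r}")


def khs_score(candidate, target) -> float:
    """Kumar-Hassebrook similarity ΣTV / (ΣT² + ΣV² − ΣTV).

    Equals 1 exactly when the vectors are identical and nonzero; raises
    when both vectors are all-zero (zero denominator).
    """
    t, v = _check_pair(candidate, target)
    tv = float(t @ v)
    denom = float(t @ t) + float(v @ v) - tv
    if denom == 0.0:
        raise ValueError("undefined similarity: zero denominator")
    return tv / denom


def select_top(scores, count: int) -> np.ndarray:
    """Indices of the ``count`` largest scores, ties to the lower index."""
    scores = np.asarray(scores, dtype=float).ravel()
    if not 1 <= count <= scores.size:
        raise ValueError(f"count must lie in [1, {scores.size}], got {count}")
    order = np.argsort(-scores, kind="stable")  # stable sort: lower index wins ties
    return order[:count]


class CongruenceKHSSelector(SelectorMixin, BaseEstimator):
    """Congruence-coefficient then Kumar-Hassebrook cascade selector.

    Parameters
    ----------
    o : stage-1 survivor count; default ceil(0.6·n).
    z : final selected count; default ceil(0.5·o).  Must satisfy
        n > o > z >= 1.
    rank_by_abs : rank stage 1 by \\|score\\| (default), so features
        perfectly anti-aligned with the target still survive.
    congruence_form : "tucker" or "unscaled" (see :func:`congruence_score`).

    Attributes
    ----------
    stage1_scores_ : congruence score per original column.
    stage1_kept_ : the o surviving columns, descending score order.
    stage2_scores_ : Kumar-Hassebrook score per survivor (same order as
        ``stage1_kept_``).
    stage2_kept_ : the z selected original columns, descending stage-2
        score order.

    Columns with zero norm cannot carry signal and score 0 in both stages.
    """

    def __init__(self, o=None, z=None, rank_by_abs=True, congruence_form="tucker"):
        self.o = o
        self.z = z
        self.rank_by_abs = rank_by_abs
        self.congruence_form = congruence_form

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float, ensure_min_samples=2)
        if not np.isin(y, [0, 1]).all():
            raise ValueError("target must be binary {0, 1}")
        n = X.shape[1]
        o = self.o if self.o is not None else math.ceil(0.6 * n)
        z = self.z if self.z is not None else math.ceil(0.5 * o)
        if not (n > o > z >= 1):
            raise ValueError(f"need n > o > z >= 1, got n={n}, o={o}, z={z}")
        target = y.astype(float)

        def safe(scorer, col):
            return 0.0 if not np.any(col) else scorer(col, target)

        s1 = np.array([safe(
            lambda c, t: congruence_score(c, t, self.congruence_form), X[:, j]
        ) for j in range(n)])
        rank_key = np.abs(s1) if self.rank_by_abs else s1
        kept1 = select_top(rank_key, o)
        s2 = np.array([safe(khs_score, X[:, j]) for j in kept1])
        kept2 = kept1[select_top(s2, z)]

        self.stage1_scores_ = s1
        self.stage1_kept_ = kept1
        self.stage2_scores_ = s2
        self.stage2_kept_ = kept2
        self.o_ = o
        self.z_ = z
        self.n_features_in_ = n
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "stage2_kept_")
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.stage2_kept_] = True
        return mask

    def report(self, column_names=None) -> "pd.DataFrame":
        """Per-column score table (stage scores and kept flags)."""
        import pandas as pd

        check_is_fitted(self, "stage2_kept_")
        n = self.n_features_in_
        names = list(column_names) if column_names is not None else [f"col{i}" for i in range(n)]
        s2 = np.full(n, np.nan)
        s2[self.stage1_kept_] = self.stage2_scores_
        return pd.DataFrame({
            "column": names,
            "stage1_score": self.stage1_scores_,
            "stage1_kept": np.isin(np.arange(n), self.stage1_kept_),
            "stage2_score": s2,
            "stage2_kept": self._get_support_mask(),
        })


def cascade_select(
    data: TabularDataset, o: int | None = None, z: int | None = None, **kwargs
) -> tuple[TabularDataset, CongruenceKHSSelector]:
    """Run the cascade on a fully imputed dataset.

    Returns the dataset restricted to the z selected columns (original
    column order) and the fitted selector with the full score record.
    """
    if data.missing_mask.any():
        raise ValueError("dataset must be fully imputed before selection")
    sel = CongruenceKHSSelector(o=o, z=z, **kwargs).fit(data.values, data.labels)
    return data.restrict(sel.stage2_kept_), sel
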