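"""Tabular clinical dataset container and CSV round trip.

Values are held as a float matrix; categorical attributes are stored as
non-negative integer category codes, missing entries as NaN (the
``missing_mask``).  Labels are binary after binarization: 0 = normal,
1 = abnormal.  Clinical sources such as the UCI heart-disease files
grade disease presence 0-4; by default any grade >= 1 maps to class 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["TabularDataset", "read_csv", "write_csv", "binarize_labels"]

NUMERIC = "numeric"
CATEGORICAL = "categorical"


def binarize_labels(raw: np.ndarray, rule: str = "zero-vs-rest") -> np.ndarray:
    """Collapse multi-grade disease labels to {0, 1}.

    ``zero-vs-rest``: grade 0 -> 0 (normal), any grade >= 1 -> 1 (abnormal).
    ``identity``: labels must already be binary.
    """
    raw = np.asarray(raw)
    if rule == "zero-vs-rest":
        return (np.asarray(raw, dtype=float) > 0).astype(int)
    if rule == "identity":
        out = np.asarray(raw, dtype=int)
        if not np.isin(out, [0, 1]).all():
            raise ValueError("identity binarization requires labels in {0, 1}")
        return out
    raise ValueError(f"unknown binarization rule {rule!r}")


@dataclass
class TabularDataset:
    """k patients × n mixed-type attributes plus a binary outcome."""

    values: np.ndarray                  # (k, n) float; NaN marks missing
    attribute_types: list[str]          # "numeric" | "categorical" per column
    labels: np.ndarray                  # (k,) ints in {0, 1}
    column_names: list[str]
    raw_labels: np.ndarray | None = None  # pre-binarization grades, if any

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        k, n = self.values.shape
        if k < 2 or n < 1:
            raise ValueError("need at least 2 rows and 1 column")
        if len(self.attribute_types) != n:
            raise ValueError("attribute_types length must equal the column count")
        if any(t not in (NUMERIC, CATEGORICAL) for t in self.attribute_types):
            raise ValueError("attribute types must be 'numeric' or 'categorical'")
        if self.labels.shape != (k,):
            raise ValueError("labels length must equal the row count")
        if not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be binary (apply binarize_labels first)")
        if len(self.column_names) != n:
            raise ValueError("column_names length must equal the column count")

    # -- basic views ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def numeric_columns(self) -> np.ndarray:
        return np.array([i for i, t in enumerate(self.attribute_types) if t == NUMERIC], dtype=int)

    @property
    def categorical_columns(self) -> np.ndarray:
        return np.array(
            [i for i, t in enumerate(self.attribute_types) if t == CATEGORICAL], dtype=int
        )

    def copy(self) -> "TabularDataset":
        return replace(
            self,
            values=self.values.copy(),
            attribute_types=list(self.attribute_types),
            labels=self.labels.copy(),
            column_names=list(self.column_names),
        )

    def with_values(self, values: np.ndarray) -> "TabularDataset":
        return replace(self, values=np.asarray(values, dtype=float))

    def restrict(self, columns) -> "TabularDataset":
        """Dataset limited to the given columns (original order preserved)."""
        cols = np.sort(np.asarray(columns, dtype=int))
        return TabularDataset(
            values=self.values[:, cols],
            attribute_types=[self.attribute_types[i] for i in cols],
            labels=self.labels,
            column_names=[self.column_names[i] for i in cols],
            raw_labels=self.raw_labels,
        )

    def subset_rows(self, rows) -> "TabularDataset":
        rows = np.asarray(rows, dtype=int)
        return TabularDataset(
            values=self.values[rows],
            attribute_types=list(self.attribute_types),
            labels=self.labels[rows],
            column_names=list(self.column_names),
            raw_labels=None if self.raw_labels is None else self.raw_labels[rows],
        )


def _infer_types(df: pd.DataFrame) -> list[str]:
    """A column that parses fully as numbers with >10 distinct observed
    values is numeric; small-cardinality or non-numeric columns are
    categorical."""
    types = []
    for col in df.columns:
        series = pd.to_numeric(df[col], errors="coerce")
        observed = series.dropna()
        parseable = observed.size == df[col].notna().sum()
        if parseable and observed.nunique() > 10:
            types.append(NUMERIC)
        else:
            types.append(CATEGORICAL)
    return types


def read_csv(
    path,
    sentinel: str = "?",
    label_column: str | None = None,
    attribute_types: list[str] | None = None,
    binarize: str = "zero-vs-rest",
) -> TabularDataset:
    """Load a patients × attributes CSV into a :class:`TabularDataset`.

    The header row supplies column names; ``label_column`` defaults to the
    last column.  Entries equal to ``sentinel`` become missing.  Category
    strings are mapped to integer codes in sorted order.
    """
    df = pd.read_csv(path, na_values=[sentinel], keep_default_na=True, comment="#",
                     skipinitialspace=True)
    if label_column is None:
        label_column = df.columns[-1]
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found")
    raw_labels = pd.to_numeric(df[label_column], errors="raise").to_numpy()
    if np.isnan(raw_labels).any():
        raise ValueError("labels may not be missing")
    feats = df.drop(columns=[label_column])
    if attribute_types is None:
        attribute_types = _infer_types(feats)
    if len(attribute_types) != feats.shape[1]:
        raise ValueError("attribute_types length must match the feature count")

    values = np.empty(feats.shape, dtype=float)
    for j, col in enumerate(feats.columns):
        series = feats[col]
        numeric = pd.to_numeric(series, errors="coerce")
        if numeric.notna().sum() == series.notna().sum():
            values[:, j] = numeric.to_numpy(dtype=float)
        else:  # string categories -> deterministic codes by sorted level
            levels = sorted(series.dropna().unique())
            mapping = {lvl: i for i, lvl in enumerate(levels)}
            values[:, j] = series.map(mapping).to_numpy(dtype=float)

    return TabularDataset(
        values=values,
        attribute_types=list(attribute_types),
        labels=binarize_labels(raw_labels, binarize),
        column_names=list(feats.columns),
        raw_labels=raw_labels,
    )


def write_csv(path, data: TabularDataset, sentinel: str = "?", provenance: str | None = None) -> None:
    """Write the dataset back to CSV with the sentinel at missing entries."""
    df = pd.DataFrame(data.values, columns=data.column_names)
    for j, t in enumerate(data.attribute_types):
        if t == CATEGORICAL:
            col = data.column_names[j]
            observed = df[col].notna()
            df.loc[observed, col] = df.loc[observed, col].astype(int)
    df["label"] = data.labels if data.raw_labels is None else data.raw_labels
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        df.to_csv(fh, index=False, na_rep=sentinel)
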