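"""Tabular cleaning, min-max scaling and explained-variance PCA.

The cleaning pass drops rows with missing cells, exact-duplicate rows and
z-score outliers (default cut |z| > 3 on continuous columns), coercing
string-typed columns to numeric where possible, and returns a report that
reconciles every dropped row.

PCA is computed on standardized columns (mean 0, sd 1) from the
population covariance ``C = X^T X / n`` (the ``1/n`` convention, not
``1/(n-1)``), with the retained component count chosen as the smallest
``m`` whose cumulative explained-variance ratio reaches the
``n_components`` threshold in (0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "CleaningReport",
    "PCAProjection",
    "DataError",
    "clean_table",
    "min_max_normalize",
    "normalize_table",
    "fit_pca",
    "select_components",
    "project",
    "sweep_n_components",
]


class DataError(ValueError):
    """Raised for unusable input tables or columns."""


@dataclass
class FeatureTable:
    """A labeled feature matrix: rows are samples, columns are features.

    ``labels`` is a binary series aligned with ``features`` (positive
    class = 1) or ``None`` for unlabeled data.
    """

    features: pd.DataFrame
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.labels is not None and len(self.labels) != len(self.features):
            raise DataError("labels and features must have equal length")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str | None = "FRI") -> "FeatureTable":
        if label_col is not None and label_col in df.columns:
            return cls(df.drop(columns=[label_col]), df[label_col])
        return cls(df.copy(), None)

    def to_dataframe(self, label_col: str = "FRI") -> pd.DataFrame:
        df = self.features.copy()
        if self.labels is not None:
            df[label_col] = self.labels
        return df

    @property
    def n_samples(self) -> int:
        return len(self.features)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]


@dataclass
class CleaningReport:
    rows_dropped_missing: int = 0
    rows_dropped_duplicate: int = 0
    rows_dropped_outlier: int = 0
    columns_coerced: list[str] = field(default_factory=list)

    @property
    def total_dropped(self) -> int:
        return (
            self.rows_dropped_missing
            + self.rows_dropped_duplicate
            + self.rows_dropped_outlier
        )


def _continuous_columns(df: pd.DataFrame) -> list[str]:
    # Binary indicator columns are excluded from the z-score rule: an
    # indicator has no meaningful standardized distance.
    out = []
    for col in df.columns:
        values = set(df[col].dropna().unique())
        if not values <= {0, 1}:
            out.append(col)
    return out


def clean_table(
    raw: pd.DataFrame | FeatureTable,
    z_threshold: float = 3.0,
    label_col: str = "FRI",
) -> tuple[FeatureTable, CleaningReport]:
    """Coerce, then drop missing, duplicate and outlier rows in order."""
    if z_threshold <= 0:
        raise ValueError("z_threshold must be positive")
    if isinstance(raw, FeatureTable):
        df = raw.to_dataframe(label_col)
        has_label = raw.labels is not None
    else:
        df = raw.copy()
        has_label = label_col in df.columns
    report = CleaningReport()

    for col in df.columns:
        if df[col].dtype == object:
            coerced = pd.to_numeric(df[col], errors="coerce")
            originally_present = df[col].notna()
            if coerced[originally_present].isna().all():
                raise DataError(f"column {col!r} cannot be coerced to numeric")
            df[col] = coerced.astype(float)
            report.columns_coerced.append(col)

    n0 = len(df)
    df = df.dropna()
    report.rows_dropped_missing = n0 - len(df)

    n1 = len(df)
    df = df.drop_duplicates(keep="first")
    report.rows_dropped_duplicate = n1 - len(df)

    n2 = len(df)
    feature_cols = [c for c in df.columns if c != label_col]
    cont = _continuous_columns(df[feature_cols])
    if cont and len(df) > 1:
        sub = df[cont].to_numpy(dtype=float)
        std = sub.std(axis=0)
        mean = sub.mean(axis=0)
        safe = std > 0
        z = np.zeros_like(sub)
        z[:, safe] = (sub[:, safe] - mean[safe]) / std[safe]
        keep = np.all(np.abs(z) <= z_threshold, axis=1)
        df = df.loc[keep]
    report.rows_dropped_outlier = n2 - len(df)

    table = FeatureTable.from_dataframe(df, label_col if has_label else None)
    return table, report


def min_max_normalize(
    column: Sequence[float], target_range: tuple[float, float] = (0.0, 1.0)
) -> np.ndarray:
    """Affinely map a column onto ``target_range`` via its min and max.

    A constant column maps to the lower bound of the range.
    """
    x = np.asarray(column, dtype=float)
    if x.size == 0:
        raise DataError("cannot normalize an empty column")
    lo, hi = target_range
    if not lo < hi:
        raise ValueError("target_range must be increasing")
    mn, mx = x.min(), x.max()
    if mx == mn:
        return np.full_like(x, lo)
    unit = (x - mn) / (mx - mn)
    return lo + unit * (hi - lo)


def normalize_table(
    table: FeatureTable, target_range: tuple[float, float] = (0.0, 1.0)
) -> tuple[FeatureTable, pd.DataFrame]:
    """Min-max scale every feature column; returns (table, min/max params)."""
    scaled = table.features.copy()
    params = pd.DataFrame(index=table.features.columns, columns=["min", "max"], dtype=float)
    for col in table.features.columns:
        vals = table.features[col].to_numpy(dtype=float)
        params.loc[col] = [vals.min(), vals.max()]
        scaled[col] = min_max_normalize(vals, target_range)
    return FeatureTable(scaled, table.labels), params


@dataclass
class PCAProjection:
    """Standardization parameters plus the eigendecomposition of C = X^T X/n."""

    components: np.ndarray  # (p, p) loadings, one eigenvector per column
    eigenvalues: np.ndarray  # descending, length p
    explained_variance_ratio: np.ndarray  # sums to 1 over all p
    mean: np.ndarray
    scale: np.ndarray
    feature_names: list[str]
    excluded_columns: list[str] = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def standardize(self, df: pd.DataFrame) -> np.ndarray:
        x = df[self.feature_names].to_numpy(dtype=float)
        return (x - self.mean) / self.scale


def fit_pca(table: FeatureTable) -> PCAProjection:
    """Standardize columns, eigendecompose the 1/n covariance matrix."""
    df = table.features
    if len(df) < 2 or df.shape[1] < 1:
        raise DataError("PCA needs at least 2 samples and 1 feature")
    x = df.to_numpy(dtype=float)
    std = x.std(axis=0)
    excluded = [c for c, s in zip(df.columns, std) if s == 0.0]
    if excluded:
        warnings.warn(
            f"excluding zero-variance columns from PCA: {excluded}", stacklevel=2
        )
    keep = [c for c in df.columns if c not in excluded]
    x = df[keep].to_numpy(dtype=float)
    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    z = (x - mean) / scale
    cov = z.T @ z / len(z)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    ratio = eigvals / eigvals.sum()
    return PCAProjection(
        components=eigvecs,
        eigenvalues=eigvals,
        explained_variance_ratio=ratio,
        mean=mean,
        scale=scale,
        feature_names=list(keep),
        excluded_columns=excluded,
    )


def select_components(proj: PCAProjection, n_components: float) -> int:
    """Smallest m whose cumulative explained-variance ratio reaches the threshold."""
    if not 0.0 < n_components <= 1.0:
        raise ValueError("n_components must be in (0, 1]")
    if n_components >= 1.0:
        return proj.n_features
    cum = np.cumsum(proj.explained_variance_ratio)
    return int(np.searchsorted(cum, n_components) + 1)


def project(proj: PCAProjection, table: FeatureTable, m: int) -> FeatureTable:
    """Project a table onto the leading ``m`` principal components."""
    if not 1 <= m <= proj.n_features:
        raise ValueError(f"m must be in [1, {proj.n_features}]")
    z = proj.standardize(table.features)
    scores = z @ proj.components[:, :m]
    cols = [f"PC{i + 1}" for i in range(m)]
    out = pd.DataFrame(scores, columns=cols, index=table.features.index)
    return FeatureTable(out, table.labels)


def sweep_n_components(
    table: FeatureTable,
    thresholds: Iterable[float],
    model_fitness: Callable[[FeatureTable], float],
    seed: int | None = None,
) -> pd.DataFrame:
    """Error-vs-retained-components stabilization curve.

    For each explained-variance threshold, selects ``m`` components,
    projects the table and evaluates ``model_fitness`` (a callable
    returning a held-out test error) on the reduced table.  ``seed`` is
    accepted for signature symmetry with seeded fitness callables.
    """
    thresholds = list(thresholds)
    if any(t2 <= t1 for t1, t2 in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly ascending")
    proj = fit_pca(table)
    rows = []
    for t in thresholds:
        m = select_components(proj, t)
        reduced = project(proj, table, m)
        rows.append({"threshold": t, "m": m, "test_error": model_fitness(reduced)})
    return pd.DataFrame(rows)
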