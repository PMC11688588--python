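"""Tabular dataset container, CSV I/O and preprocessing.

All downstream stages consume a :class:`TabularDataset`: a fully numeric
feature matrix, a {0,1} outcome vector and a per-feature schema.  The
preprocessing conventions are the ones common in clinical tabular modelling:

* two-level text features become 0/1 indicators;
* multi-level nominal features become one indicator per level, dropping the
  most frequent level as the reference;
* missing feature values are mean-imputed (missing-completely-at-random
  assumption), including in binary columns, which may therefore hold
  fractional values afterwards;
* a feature is *continuous* if it has at least 10 unique values, *discrete
  numeric* with 3-9, and *binary* with 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FeatureKind",
    "FeatureSchema",
    "TabularDataset",
    "load_dataset",
    "classify_features",
    "impute_missing_mean",
    "subsample",
]

#: unique-value count at and above which a feature counts as continuous
CONTINUOUS_MIN_UNIQUE = 10

_NA_VALUES = ["", "NA"]


class FeatureKind(str, Enum):
    """Feature type used by the dataset profile (continuous % characteristic)."""

    CONTINUOUS = "continuous"
    DISCRETE_NUMERIC = "discrete_numeric"
    BINARY = "binary"


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature names with one :class:`FeatureKind` each."""

    names: tuple[str, ...]
    kinds: tuple[FeatureKind, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.kinds):
            raise ValueError("names and kinds must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    def __len__(self) -> int:
        return len(self.names)

    @property
    def pct_continuous(self) -> float:
        """Percentage of features typed continuous."""
        if not self.names:
            return 0.0
        n_cont = sum(k is FeatureKind.CONTINUOUS for k in self.kinds)
        return 100.0 * n_cont / len(self.names)

    def to_dict(self) -> dict[str, str]:
        return {n: k.value for n, k in zip(self.names, self.kinds)}


@dataclass
class TabularDataset:
    """Numeric feature matrix ``X``, binary outcome ``y`` and schema.

    ``y`` holds values in {0, 1}; either label may be the minority class.
    ``X`` may contain NaN before :func:`impute_missing_mean` and must not
    afterwards.
    """

    X: np.ndarray
    y: np.ndarray
    schema: FeatureSchema

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")
        if self.X.shape[1] != len(self.schema):
            raise ValueError("X column count does not match schema")
        uniq = set(np.unique(self.y).tolist())
        if not uniq <= {0, 1}:
            raise ValueError(f"y must contain only 0/1, got {sorted(uniq)}")
        self.y = self.y.astype(int)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.X).any())

    def to_frame(self, outcome_name: str = "outcome") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.schema.names))
        df[outcome_name] = self.y
        return df

    def to_csv(self, path: str | Path, outcome_name: str = "outcome") -> None:
        self.to_frame(outcome_name).to_csv(path, index=False)


def _encode_outcome(col: pd.Series) -> np.ndarray:
    """Map a two-level outcome to {0,1}; the lexicographically/numerically
    larger raw label becomes 1."""
    levels = sorted(col.dropna().unique().tolist(), key=lambda v: (str(type(v)), v))
    if len(levels) != 2:
        raise ValueError(
            f"outcome must have exactly 2 distinct non-missing values, got {len(levels)}"
        )
    return (col == levels[1]).astype(int).to_numpy()


def _encode_features(df: pd.DataFrame) -> pd.DataFrame:
    """Numeric passthrough; 2-level text -> 0/1; multi-level nominal ->
    one indicator per non-reference level (reference = most frequent)."""
    out: dict[str, pd.Series] = {}
    for name in df.columns:
        col = df[name]
        numeric = pd.to_numeric(col, errors="coerce")
        # treat as numeric if every non-missing raw value parsed
        if numeric.notna().sum() == col.notna().sum():
            out[name] = numeric
            continue
        levels = col.dropna().astype(str)
        uniq = levels.value_counts()
        if len(uniq) < 2:
            raise ValueError(f"text feature {name!r} has fewer than 2 levels")
        if len(uniq) == 2:
            hi = sorted(uniq.index)[1]
            enc = (levels == hi).astype(float)
            out[name] = enc.reindex(col.index)
        else:
            ref = uniq.index[0]  # most frequent level is the reference
            for lev in sorted(l for l in uniq.index if l != ref):
                enc = (levels == lev).astype(float)
                out[f"{name}={lev}"] = enc.reindex(col.index)
    return pd.DataFrame(out)


def load_dataset(path: str | Path, outcome_name: str) -> TabularDataset:
    """Read a CSV with a header row into a :class:`TabularDataset`.

    Parameters
    ----------
    path:
        CSV file; missing cells encoded as empty fields or ``NA``.
    outcome_name:
        Column holding the binary outcome (exactly two distinct non-missing
        values; text or numeric).

    Raises
    ------
    ValueError
        If the file is empty, the outcome column is absent, or the outcome
        does not have exactly two levels.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, na_values=_NA_VALUES, keep_default_na=True)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty file: {path}") from exc
    if outcome_name not in df.columns:
        raise ValueError(f"outcome column {outcome_name!r} not found in {path}")
    if df[outcome_name].isna().any():
        n_drop = int(df[outcome_name].isna().sum())
        warnings.warn(f"dropping {n_drop} rows with missing outcome")
        df = df.loc[df[outcome_name].notna()]
    y = _encode_outcome(df[outcome_name])
    feats = _encode_features(df.drop(columns=[outcome_name]))
    X = feats.to_numpy(dtype=float)
    ds = TabularDataset(
        X=X,
        y=y,
        schema=FeatureSchema(
            names=tuple(feats.columns),
            kinds=tuple(FeatureKind.BINARY for _ in feats.columns),
        ),
    )
    ds.schema = classify_features(ds)
    return ds


def classify_features(dataset: TabularDataset) -> FeatureSchema:
    """Type each feature by its number of unique (non-missing) values.

    >=10 unique values -> continuous; 3-9 -> discrete numeric; 2 -> binary.
    A constant column is degenerate: it is typed binary and a warning is
    emitted.
    """
    kinds = []
    for j, name in enumerate(dataset.schema.names):
        col = dataset.X[:, j]
        n_unique = len(np.unique(col[~np.isnan(col)]))
        if n_unique >= CONTINUOUS_MIN_UNIQUE:
            kinds.append(FeatureKind.CONTINUOUS)
        elif n_unique >= 3:
            kinds.append(FeatureKind.DISCRETE_NUMERIC)
        elif n_unique == 2:
            kinds.append(FeatureKind.BINARY)
        else:
            warnings.warn(f"feature {name!r} is constant; treated as binary-degenerate")
            kinds.append(FeatureKind.BINARY)
    return FeatureSchema(names=dataset.schema.names, kinds=tuple(kinds))


def impute_missing_mean(dataset: TabularDataset) -> TabularDataset:
    """Replace every missing feature cell by its column mean over observed values.

    Idempotent; the outcome is untouched.  A fully missing column is an
    error since its mean is undefined.
    """
    X = dataset.X.copy()
    for j, name in enumerate(dataset.schema.names):
        col = X[:, j]
        mask = np.isnan(col)
        if not mask.any():
            continue
        if mask.all():
            raise ValueError(f"feature {name!r} is fully missing; cannot impute")
        col[mask] = col[~mask].mean()
    return replace(dataset, X=X)


def subsample(
    dataset: TabularDataset,
    n: int,
    seed: int,
    max_retries: int = 10,
) -> TabularDataset:
    """Draw ``n`` rows uniformly without replacement, deterministically.

    The draw is retried (advancing the generator) up to ``max_retries`` times
    if it misses one outcome class — relevant for small ``n`` under heavy
    class imbalance — and errors if a two-class subsample is never obtained.
    """
    if n > dataset.n_samples:
        raise ValueError(f"n={n} exceeds dataset size {dataset.n_samples}")
    if n < 2:
        raise ValueError("n must be at least 2")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        idx = rng.choice(dataset.n_samples, size=n, replace=False)
        y = dataset.y[idx]
        if y.min() != y.max():
            return replace(dataset, X=dataset.X[idx], y=y)
    raise ValueError(
        f"subsample of n={n} contained a single outcome class after "
        f"{max_retries} retries"
    )
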