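"""Tabular water-quality data: reading, cleaning, normalization, splitting.

A dataset is one row per monitoring sample with seven numeric indicators —
dissolved oxygen (mg/L), temperature (deg C), turbidity (NTU), ammonia
nitrogen (mg/L), permanganate index (mg/L), pH and total dissolved solids
(mg/L) — plus an optional ordinal quality class label 1..6 (I .. poor V).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .errors import (
    ConfigError,
    DegenerateColumnError,
    InputError,
    SchemaError,
    StratificationError,
    ValidationError,
)
from .standards import NAME_TO_CLASS

log = logging.getLogger(__name__)

#: Canonical indicator order; recorded and preserved everywhere.
INDICATORS: tuple[str, ...] = ("do", "temp", "turbidity", "nh3n", "codmn", "ph", "tds")
LABEL_COLUMN = "label"

#: Default CSV column names (internal name -> file column name).
DEFAULT_SCHEMA: dict[str, str] = {name: name for name in (*INDICATORS, LABEL_COLUMN)}


@dataclass
class Dataset:
    """Ordered collection of water samples (indicator columns + optional label)."""

    frame: pd.DataFrame
    n_dropped: int = 0
    indicator_names: tuple[str, ...] = field(default=INDICATORS)

    def __post_init__(self) -> None:
        missing = [c for c in self.indicator_names if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"dataset frame lacks indicator columns: {missing}")
        if len(self.frame) < 2:
            raise ValidationError("a dataset needs at least two samples")

    @property
    def m(self) -> int:
        return len(self.frame)

    @property
    def n(self) -> int:
        return len(self.indicator_names)

    @property
    def has_labels(self) -> bool:
        return LABEL_COLUMN in self.frame.columns

    @property
    def labels(self) -> np.ndarray:
        if not self.has_labels:
            raise ValidationError("dataset has no label column")
        return self.frame[LABEL_COLUMN].to_numpy(dtype=int)

    @property
    def X(self) -> pd.DataFrame:
        return self.frame[list(self.indicator_names)]

    def features(self, names: Sequence[str]) -> pd.DataFrame:
        unknown = [n for n in names if n not in self.indicator_names]
        if unknown:
            raise ValidationError(f"unknown indicators: {unknown}")
        return self.frame[list(names)]

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def _coerce_labels(series: pd.Series) -> pd.Series:
    """Accept labels as integers 1..6 or roman-style names (I .. poor V)."""

    def one(v: object) -> int:
        if isinstance(v, str):
            s = v.strip()
            if s in NAME_TO_CLASS:
                return NAME_TO_CLASS[s]
            v = s
        try:
            iv = int(float(v))  # type: ignore[arg-type]
        except (TypeError, ValueError) as exc:
            raise InputError(f"unparseable class label {v!r}") from exc
        if iv not in range(1, 7):
            raise InputError(f"class label must be in 1..6, got {iv}")
        return iv

    return series.map(one)


def read_dataset(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> Dataset:
    """Read a CSV of monitoring records, dropping (and counting) bad rows.

    ``schema`` maps internal indicator names to the file's column names; the
    label column is optional.  Rows with a missing or unparseable indicator
    value are dropped and counted (``Dataset.n_dropped``) — the cleaning step
    of the assessment workflow.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"empty input file: {path}") from exc
    if raw.empty:
        raise InputError(f"no data rows in {path}")

    for internal in INDICATORS:
        if colmap[internal] not in raw.columns:
            raise SchemaError(f"missing required column {colmap[internal]!r} (for {internal!r})")

    frame = pd.DataFrame(index=raw.index)
    for internal in INDICATORS:
        frame[internal] = pd.to_numeric(raw[colmap[internal]], errors="coerce")
    frame = frame.replace([np.inf, -np.inf], np.nan)
    keep = frame.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("read_dataset: dropped %d row(s) with missing/unparseable indicators", n_dropped)
    frame = frame.loc[keep]

    label_col = colmap.get(LABEL_COLUMN, LABEL_COLUMN)
    if label_col in raw.columns:
        frame[LABEL_COLUMN] = _coerce_labels(raw.loc[keep, label_col])

    return Dataset(frame.reset_index(drop=True), n_dropped=n_dropped)


def min_max_normalize(values: Iterable[float]) -> np.ndarray:
    """Linear rescale to [0, 1]: y_i = (x_i - min x) / (max x - min x).

    Raises :class:`DegenerateColumnError` for a constant series — the caller
    decides whether to drop the indicator.
    """
    x = np.asarray(list(values) if not isinstance(values, np.ndarray) else values, dtype=float)
    if x.ndim != 1:
        raise ValidationError("min_max_normalize expects a 1-D series")
    if x.size < 2:
        raise ValidationError("min_max_normalize needs at least two values")
    if not np.all(np.isfinite(x)):
        raise ValidationError("min_max_normalize: non-finite values")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateColumnError("constant series: max == min")
    return (x - lo) / (hi - lo)


@dataclass(frozen=True)
class FittedMinMax:
    """Per-feature min-max parameters fitted on training data.

    Applying the transform to unseen data uses the *training* extremes, so
    test values may fall outside [0, 1]; they are deliberately not clipped.
    """

    feature_names: tuple[str, ...]
    mins: np.ndarray
    ranges: np.ndarray

    @classmethod
    def fit(cls, X: pd.DataFrame) -> "FittedMinMax":
        arr = X.to_numpy(dtype=float)
        if arr.shape[0] < 2:
            raise ValidationError("need at least two rows to fit a scaler")
        mins = arr.min(axis=0)
        ranges = arr.max(axis=0) - mins
        bad = np.flatnonzero(ranges == 0)
        if bad.size:
            names = [X.columns[i] for i in bad]
            raise DegenerateColumnError(f"constant feature column(s): {names}")
        return cls(tuple(X.columns), mins, ranges)

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        if tuple(X.columns) != self.feature_names:
            raise ValidationError(
                f"feature mismatch: expected {self.feature_names}, got {tuple(X.columns)}"
            )
        return (X.to_numpy(dtype=float) - self.mins) / self.ranges


def stratified_split_indices(
    labels: np.ndarray, test_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Row indices of a seeded, label-stratified train/test partition.

    The partition depends only on the label sequence and the seed, never on
    the indicator values.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ConfigError(f"test_fraction must be in (0, 1), got {test_fraction}")
    y = np.asarray(labels)
    counts = pd.Series(y).value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise StratificationError(f"class(es) {small} have fewer than 2 samples")
    idx = np.arange(y.size)
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=seed, stratify=y
    )
    train_idx.sort()
    test_idx.sort()
    return train_idx, test_idx


def stratified_split(
    ds: Dataset, test_fraction: float = 0.2, seed: int = 0
) -> tuple[Dataset, Dataset]:
    """Seeded, label-stratified train/test partition (disjoint, union = ds)."""
    train_idx, test_idx = stratified_split_indices(ds.labels, test_fraction, seed)
    mk = lambda ix: Dataset(ds.frame.iloc[ix].reset_index(drop=True))
    return mk(train_idx), mk(test_idx)
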