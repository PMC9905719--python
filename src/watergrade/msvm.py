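"""One-vs-one multiclass SVM with PSO-tuned kernel hyperparameters.

For k classes, k(k-1)/2 binary soft-margin SVMs are trained, one per class
pair, on min-max-scaled features (scaler fitted on the training split only).
Prediction is by majority vote; ties are broken by the largest sum of signed
decision values among the tied classes, then by the lowest class id.

Kernels follow the usual tabulated forms: linear (x.y), RBF
exp(-||x - y||^2 / r^2) — i.e. gamma = 1/r^2 in the scikit-learn
parameterization — and polynomial ((x.y) + 1)^d.  The binary quadratic
program is solved by scikit-learn's SVC; the OVO construction, scaling,
voting and tuning live here.

Hyperparameters (C, and r for the RBF) are tuned by the particle swarm over
log10-scaled boxes, minimizing a stratified K-fold cross-validated error
rate on the training data.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import ConfigError, TrainingError, ValidationError
from .io import FittedMinMax
from .pso import PsoConfig, optimize

log = logging.getLogger(__name__)

KERNEL_KINDS = ("linear", "rbf", "polynomial")

#: Default tuning boxes on log10 scale (C and RBF width r) and linear degree.
DEFAULT_SEARCH_BOUNDS: dict[str, tuple[float, float]] = {
    "log10_C": (-2.0, 3.0),
    "log10_r": (-3.0, 1.0),
    "degree": (1.0, 5.0),
}


@dataclass(frozen=True)
class KernelSpec:
    """Kernel kind plus exactly the parameters that kernel takes."""

    kind: str
    C: float
    r: float | None = None
    d: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in KERNEL_KINDS:
            raise ValidationError(f"unknown kernel kind {self.kind!r}")
        if not self.C > 0:
            raise ValidationError(f"penalty C must be positive, got {self.C}")
        if self.kind == "linear" and (self.r is not None or self.d is not None):
            raise ValidationError("linear kernel takes only C")
        if self.kind == "rbf":
            if self.r is None or not self.r > 0:
                raise ValidationError("rbf kernel needs a positive width r")
            if self.d is not None:
                raise ValidationError("rbf kernel takes no degree")
        if self.kind == "polynomial":
            if self.d is None or self.d < 1:
                raise ValidationError("polynomial kernel needs degree d >= 1")
            if self.r is not None:
                raise ValidationError("polynomial kernel takes no width r")

    def make_svc(self) -> SVC:
        if self.kind == "linear":
            return SVC(kernel="linear", C=self.C)
        if self.kind == "rbf":
            # exp(-||x-y||^2 / r^2)  ->  gamma = 1 / r^2
            return SVC(kernel="rbf", C=self.C, gamma=1.0 / (self.r ** 2))
        return SVC(kernel="poly", C=self.C, degree=int(self.d), gamma=1.0, coef0=1.0)


@dataclass
class OvoModel:
    """k(k-1)/2 trained binary SVMs keyed by (lower class, higher class)."""

    classes: tuple[int, ...]
    binary_models: dict[tuple[int, int], SVC]
    kernel: KernelSpec
    feature_names: tuple[str, ...]
    scaler: FittedMinMax

    schema_version: int = field(default=1)

    @property
    def k(self) -> int:
        return len(self.classes)

    def decision_table(self, X: pd.DataFrame) -> dict[tuple[int, int], np.ndarray]:
        """Signed decision values per pair; positive favours the higher class."""
        Xs = self.scaler.transform(self._check_features(X))
        return {pair: svc.decision_function(Xs) for pair, svc in self.binary_models.items()}

    def _check_features(self, X: pd.DataFrame) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            if tuple(X.columns) != self.feature_names:
                raise ValidationError(
                    f"feature mismatch: model expects {self.feature_names}, got {tuple(X.columns)}"
                )
            return X
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != len(self.feature_names):
            raise ValidationError("feature matrix width does not match the model")
        return pd.DataFrame(arr, columns=list(self.feature_names))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return vote(self.classes, self.decision_table(X))

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "schema_version": self.schema_version,
                "classes": self.classes,
                "binary_models": self.binary_models,
                "kernel": self.kernel,
                "feature_names": self.feature_names,
                "scaler": self.scaler,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "OvoModel":
        d = joblib.load(path)
        if d.get("schema_version") != 1:
            raise ValidationError(f"unsupported model archive version {d.get('schema_version')}")
        return cls(
            classes=d["classes"],
            binary_models=d["binary_models"],
            kernel=d["kernel"],
            feature_names=d["feature_names"],
            scaler=d["scaler"],
        )


def vote(
    classes: Sequence[int], decisions: Mapping[tuple[int, int], np.ndarray]
) -> np.ndarray:
    """Majority vote over pairwise decisions with deterministic tie-breaking.

    ``decisions[(a, b)]`` (a < b) holds signed values, one per sample:
    positive votes for b, otherwise a.  Ties on vote count are broken by the
    largest accumulated signed decision value among the tied classes, then by
    the lowest class id.
    """
    classes = tuple(classes)
    idx = {c: i for i, c in enumerate(classes)}
    n = len(next(iter(decisions.values())))
    votes = np.zeros((n, len(classes)))
    scores = np.zeros((n, len(classes)))
    for (a, b), d in decisions.items():
        d = np.asarray(d, dtype=float)
        b_wins = d > 0
        votes[b_wins, idx[b]] += 1
        votes[~b_wins, idx[a]] += 1
        scores[:, idx[a]] -= d
        scores[:, idx[b]] += d

    out = np.empty(n, dtype=int)
    class_arr = np.array(classes)
    for i in range(n):
        top = votes[i] == votes[i].max()
        cand = np.flatnonzero(top)
        if cand.size > 1:
            best = scores[i, cand] == scores[i, cand].max()
            cand = cand[best]
        out[i] = int(class_arr[cand.min()])
    return out


def train_ovo(X: pd.DataFrame, y: np.ndarray, kernel: KernelSpec) -> OvoModel:
    """Fit one binary SVM per class pair on min-max scaled features."""
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
        X.columns = [f"f{i}" for i in range(X.shape[1])]
    y = np.asarray(y, dtype=int)
    if len(X) != len(y):
        raise ValidationError("X and y lengths differ")
    classes = tuple(sorted(set(int(c) for c in y)))
    if len(classes) < 2:
        raise TrainingError("training data contains a single class")
    counts = {c: int((y == c).sum()) for c in classes}
    small = [c for c, n in counts.items() if n < 2]
    if small:
        raise TrainingError(f"class(es) {small} have fewer than 2 training samples")

    scaler = FittedMinMax.fit(X)
    Xs = scaler.transform(X)
    models: dict[tuple[int, int], SVC] = {}
    for a, b in combinations(classes, 2):
        mask = (y == a) | (y == b)
        svc = kernel.make_svc()
        svc.fit(Xs[mask], y[mask])
        models[(a, b)] = svc
    return OvoModel(
        classes=classes,
        binary_models=models,
        kernel=kernel,
        feature_names=tuple(X.columns),
        scaler=scaler,
    )


def predict(model: OvoModel, X: pd.DataFrame) -> np.ndarray:
    """Module-level alias for :meth:`OvoModel.predict`."""
    return model.predict(X)


def spec_from_position(kind: str, z: np.ndarray) -> KernelSpec:
    """Decode a PSO position into a kernel spec (log10 C, then log10 r / degree)."""
    if kind == "linear":
        return KernelSpec("linear", C=10.0 ** z[0])
    if kind == "rbf":
        return KernelSpec("rbf", C=10.0 ** z[0], r=10.0 ** z[1])
    return KernelSpec("polynomial", C=10.0 ** z[0], d=max(1, int(round(z[1]))))


def cv_fitness(
    X: pd.DataFrame,
    y: np.ndarray,
    kernel_kind: str,
    params: Sequence[float],
    folds: int = 5,
    seed: int = 0,
) -> float:
    """Stratified K-fold cross-validated error rate (1 - accuracy).

    A fold whose training part does not contain every class (so some class
    pair would be untrainable) is skipped with a log entry.
    """
    if folds < 2:
        raise ConfigError("folds must be >= 2")
    y = np.asarray(y, dtype=int)
    spec = spec_from_position(kernel_kind, np.asarray(params, dtype=float))
    all_classes = set(int(c) for c in y)
    counts = {c: int((y == c).sum()) for c in all_classes}
    if min(counts.values()) < folds:
        raise TrainingError(
            f"smallest class has {min(counts.values())} samples; cannot build {folds} folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    errors = []
    for tr, te in skf.split(np.zeros(len(y)), y):
        if set(int(c) for c in y[tr]) != all_classes:
            log.info("cv_fitness: skipping a fold lacking a class pair")
            continue
        model = train_ovo(X.iloc[tr], y[tr], spec)
        pred = model.predict(X.iloc[te])
        errors.append(float(np.mean(pred != y[te])))
    if not errors:
        raise TrainingError("every cross-validation fold was skipped")
    return float(np.mean(errors))


@dataclass
class TuneResult:
    kernel: KernelSpec
    cv_error: float
    history: np.ndarray
    iterations: int


def pso_tune(
    X: pd.DataFrame,
    y: np.ndarray,
    kernel_kind: str = "rbf",
    pso_cfg: PsoConfig | None = None,
    search_bounds: Mapping[str, tuple[float, float]] | None = None,
    folds: int = 5,
    cv_seed: int = 0,
) -> TuneResult:
    """Tune (C[, r or d]) by PSO minimizing the cross-validated error rate."""
    if kernel_kind not in KERNEL_KINDS:
        raise ValidationError(f"unknown kernel kind {kernel_kind!r}")
    bounds_map = dict(DEFAULT_SEARCH_BOUNDS)
    if search_bounds:
        bounds_map.update(search_bounds)
    if kernel_kind == "linear":
        box = (bounds_map["log10_C"],)
    elif kernel_kind == "rbf":
        box = (bounds_map["log10_C"], bounds_map["log10_r"])
    else:
        box = (bounds_map["log10_C"], bounds_map["degree"])

    if all(lo == hi for lo, hi in box):
        # search box collapsed to a single point: nothing to optimize
        z = np.array([lo for lo, _ in box])
        err = cv_fitness(X, y, kernel_kind, z, folds=folds, seed=cv_seed)
        return TuneResult(
            kernel=spec_from_position(kernel_kind, z),
            cv_error=err,
            history=np.array([err]),
            iterations=0,
        )

    if pso_cfg is None:
        pso_cfg = PsoConfig(bounds=box)
    else:
        # rebuild with the kernel's search box if the caller left bounds generic
        from dataclasses import replace

        pso_cfg = replace(pso_cfg, bounds=box)

    objective = lambda z: cv_fitness(X, y, kernel_kind, z, folds=folds, seed=cv_seed)
    res = optimize(objective, pso_cfg)
    return TuneResult(
        kernel=spec_from_position(kernel_kind, res.position),
        cv_error=res.fitness,
        history=res.history,
        iterations=res.iterations,
    )
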