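"""Weighted grey relational analysis for indicator selection.

Grey relational analysis (GRA) scores how closely each indicator series
tracks a reference series — here the ordinal quality class — through
normalized absolute differences.  Classical (Deng) GRA averages the
relational coefficients with equal weight; this module instead weights each
indicator's mean coefficient by a *combination weight* that merges a
subjective AHP weight (from a Saaty 1-9 pairwise comparison matrix) with an
objective CRITIC weight (dispersion times conflict with the other
indicators).  Indicators are then ranked by the weighted relational degree
and the top q are selected as model inputs.

Cost-type indicators (those that *fall* as water quality degrades, i.e.
dissolved oxygen) are reversed before comparison — the usual GRA "leveling"
step — so that closeness to the class series measures informativeness in the
same direction for every indicator.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateColumnError, ValidationError
from .io import Dataset, min_max_normalize

log = logging.getLogger(__name__)

#: Default orientation: "inverse" marks cost-type indicators to be reversed
#: before the grey comparison.  Dissolved oxygen is the only indicator here
#: that decreases as the class number (pollution severity) increases.
DEFAULT_ORIENTATION: dict[str, str] = {"do": "inverse"}

#: Saaty random-consistency indices for the AHP consistency ratio.
SAATY_RI: dict[int, float] = {
    1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12,
    6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49,
}


@dataclass(frozen=True)
class GreyConfig:
    """Grey-coefficient settings.

    rho
        Difference (distinguishing) coefficient in (0, 1]; 0.5 by convention.
    denominator_form
        ``standard``: coefficient denominator Δ_j(i) + ρ·Δmax (classical);
        ``literal``: Δ_j(i) + Δmax (the alternative form without ρ).
    normalize_reference
        Min-max normalize the class series before comparison so both sides
        live on [0, 1].
    orientation
        Mapping indicator -> ``direct``/``inverse``; ``inverse`` columns are
        reversed during normalization.  ``None`` means the package default
        (reverse dissolved oxygen); pass ``{}`` to disable reorientation.
    """

    rho: float = 0.5
    denominator_form: str = "standard"
    normalize_reference: bool = True
    orientation: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.rho <= 1.0:
            raise ConfigError(f"rho must be in (0, 1], got {self.rho}")
        if self.denominator_form not in ("standard", "literal"):
            raise ConfigError(f"unknown denominator_form {self.denominator_form!r}")
        if self.orientation is not None:
            bad = {k: v for k, v in self.orientation.items() if v not in ("direct", "inverse")}
            if bad:
                raise ConfigError(f"orientation values must be direct/inverse: {bad}")

    def resolved_orientation(self) -> Mapping[str, str]:
        return DEFAULT_ORIENTATION if self.orientation is None else self.orientation


class ComparisonMatrix:
    """Positive reciprocal pairwise-importance matrix on the Saaty 1-9 scale."""

    def __init__(self, values: np.ndarray | Sequence[Sequence[float]]):
        q = np.asarray(values, dtype=float)
        if q.ndim != 2 or q.shape[0] != q.shape[1]:
            raise ValidationError("comparison matrix must be square")
        if not np.all(np.isfinite(q)) or np.any(q <= 0):
            raise ValidationError("comparison matrix entries must be positive and finite")
        if not np.allclose(np.diag(q), 1.0, atol=1e-9):
            raise ValidationError("comparison matrix diagonal must be 1")
        if not np.allclose(q * q.T, 1.0, rtol=1e-6):
            raise ValidationError("comparison matrix must be reciprocal: q_jl = 1/q_lj")
        tol = 1e-9
        if np.any(q > 9 + tol) or np.any(q < 1 / 9 - tol):
            raise ValidationError("comparison entries must lie in [1/9, 9]")
        self.values = q

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @classmethod
    def equal(cls, n: int) -> "ComparisonMatrix":
        """All-ones matrix: every indicator judged equally important."""
        return cls(np.ones((n, n)))

    @classmethod
    def from_priorities(cls, w: Sequence[float]) -> "ComparisonMatrix":
        """Perfectly consistent matrix with entries w_j / w_l (CR = 0)."""
        w = np.asarray(w, dtype=float)
        if np.any(w <= 0):
            raise ValidationError("priorities must be positive")
        return cls(np.outer(w, 1.0 / w))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ComparisonMatrix":
        return cls(pd.read_csv(path, header=None).to_numpy(dtype=float))


def default_comparison_matrix() -> ComparisonMatrix:
    """Domain-informed default judgment for the seven indicators.

    The four indicators with per-class limits in the surface-water standard
    (DO, NH3-N, CODMn, TDS) are judged moderately more important (Saaty 3)
    than the advisory indicators (temperature, turbidity, pH), which carry no
    class bands.  Built as a consistent ratio matrix, so CR = 0.

    Column order follows :data:`watergrade.io.INDICATORS`:
    do, temp, turbidity, nh3n, codmn, ph, tds.
    """
    return ComparisonMatrix.from_priorities([3, 1, 1, 3, 3, 1, 3])


@dataclass(frozen=True)
class WeightVector:
    """Nonnegative per-indicator weights summing to 1."""

    w: np.ndarray
    kind: str  # "subjective" (AHP), "objective" (CRITIC) or "combined"

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if np.any(w < -1e-12):
            raise ValidationError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValidationError(f"weights must sum to 1, got {w.sum()!r}")
        object.__setattr__(self, "w", w)

    def __len__(self) -> int:
        return self.w.size


def ahp_weights(Q: ComparisonMatrix) -> tuple[WeightVector, float]:
    """Subjective weights by row-sum normalization, plus the consistency ratio.

    alpha_j = (sum of row j) / (sum of all entries).  The consistency ratio is
    the usual CR = ((lambda_max - n)/(n - 1)) / RI; values above 0.1 indicate
    incoherent judgments and are logged as a warning.
    """
    q = Q.values
    n = Q.n
    row = q.sum(axis=1)
    alpha = row / q.sum()

    lam = float(np.max(np.real(np.linalg.eigvals(q))))
    if n <= 2:
        cr = 0.0
    else:
        ci = (lam - n) / (n - 1)
        ri = SAATY_RI.get(n)
        if ri is None:
            raise ValidationError(f"no random-consistency index tabulated for n={n}")
        cr = ci / ri
    if cr > 0.1:
        log.warning("AHP consistency ratio %.3f exceeds 0.1: judgments are inconsistent", cr)
    return WeightVector(alpha, "subjective"), cr


def critic_weights(X: np.ndarray | pd.DataFrame) -> WeightVector:
    """Objective CRITIC weights from a normalized m x n matrix.

    C_j = sigma_j * sum_l (1 - r_jl) with sigma_j the column standard
    deviation and r_jl the Pearson correlation between columns; weights are
    C_j normalized to sum 1.
    """
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValidationError("CRITIC expects an m x n matrix")
    m, n = arr.shape
    if m < 3:
        raise ValidationError("CRITIC needs at least three rows")
    sigma = arr.std(axis=0, ddof=1)
    if np.any(sigma <= 1e-15):
        bad = np.flatnonzero(sigma <= 1e-15).tolist()
        raise DegenerateColumnError(f"constant column(s) at positions {bad}")
    r = np.corrcoef(arr, rowvar=False)
    conflict = np.clip(1.0 - r, 0.0, None).sum(axis=1)
    c = sigma * conflict
    total = c.sum()
    if total <= 1e-15:
        raise DegenerateColumnError("all columns perfectly correlated: zero information")
    return WeightVector(c / total, "objective")


def combine_weights(alpha: WeightVector, beta: WeightVector) -> WeightVector:
    """omega_j = (alpha_j + beta_j) / sum(alpha + beta) — i.e. their mean."""
    if len(alpha) != len(beta):
        raise ValidationError("weight vectors have different lengths")
    s = alpha.w + beta.w
    return WeightVector(s / s.sum(), "combined")


def grey_coefficients(
    reference: np.ndarray, subindices: np.ndarray, cfg: GreyConfig | None = None
) -> np.ndarray:
    """Grey relational coefficients between a reference series and each column.

    Both inputs must already be normalized to [0, 1].  Differences
    Δ_j(i) = |x_0(i) - x_j(i)| are pooled globally for Δmin / Δmax.  When every
    series is identical (Δmax = 0) all coefficients are 1 by convention.
    """
    cfg = cfg or GreyConfig()
    ref = np.asarray(reference, dtype=float)
    sub = np.asarray(subindices, dtype=float)
    if sub.ndim != 2 or ref.ndim != 1 or sub.shape[0] != ref.size:
        raise ValidationError("shape mismatch between reference and subindex matrix")
    if ref.size < 2:
        raise ValidationError("need at least two samples")
    eps = 1e-9
    for name, a in (("reference", ref), ("subindices", sub)):
        if np.any(a < -eps) or np.any(a > 1 + eps):
            raise ValidationError(f"{name} must be normalized to [0, 1]")
    delta = np.abs(ref[:, None] - sub)
    dmin, dmax = delta.min(), delta.max()
    if dmax == 0.0:
        return np.ones_like(delta)
    num = dmin + cfg.rho * dmax
    if cfg.denominator_form == "standard":
        return num / (delta + cfg.rho * dmax)
    return num / (delta + dmax)


def weighted_degree(s: np.ndarray, omega: WeightVector) -> np.ndarray:
    """Weighted relational degree r(j) = omega_j * mean_i s_j(i)."""
    s = np.asarray(s, dtype=float)
    if s.ndim != 2 or s.shape[1] != len(omega):
        raise ValidationError("coefficient matrix and weights disagree in size")
    return omega.w * s.mean(axis=0)


@dataclass
class RelationalResult:
    """Full output of the weighted relational analysis."""

    coefficients: np.ndarray           # m x n grey relational coefficients
    alpha: WeightVector                # subjective (AHP)
    beta: WeightVector                 # objective (CRITIC)
    omega: WeightVector                # combined
    degree: np.ndarray                 # weighted relational degrees r(j)
    ranking: tuple[str, ...]           # indicators by descending degree
    consistency_ratio: float
    indicator_names: tuple[str, ...] = field(default=())

    @property
    def table(self) -> pd.DataFrame:
        order = {name: k for k, name in enumerate(self.ranking)}
        df = pd.DataFrame(
            {
                "indicator": self.indicator_names,
                "mean_coefficient": self.coefficients.mean(axis=0),
                "alpha": self.alpha.w,
                "beta": self.beta.w,
                "omega": self.omega.w,
                "degree": self.degree,
            }
        )
        df["rank"] = [order[n] + 1 for n in self.indicator_names]
        return df.sort_values("rank").reset_index(drop=True)


def _normalized_matrix(ds: Dataset, orientation: Mapping[str, str]) -> np.ndarray:
    cols = []
    for name in ds.indicator_names:
        y = min_max_normalize(ds.frame[name].to_numpy(dtype=float))
        if orientation.get(name, "direct") == "inverse":
            y = 1.0 - y
        cols.append(y)
    return np.column_stack(cols)


def relational_analysis(
    ds: Dataset,
    Q: ComparisonMatrix | None = None,
    cfg: GreyConfig | None = None,
) -> RelationalResult:
    """Run the full weighted GRA pipeline on a labelled dataset.

    Normalizes every indicator column (reversing cost-type ones), normalizes
    the class series, computes grey coefficients against it, builds the
    AHP + CRITIC combination weights and ranks indicators by weighted degree.
    Ties are broken by original column order (stable sort).
    """
    cfg = cfg or GreyConfig()
    if Q is None:
        Q = default_comparison_matrix() if ds.n == 7 else ComparisonMatrix.equal(ds.n)
    if Q.n != ds.n:
        raise ValidationError(f"comparison matrix is {Q.n}x{Q.n} but dataset has {ds.n} indicators")

    X = _normalized_matrix(ds, cfg.resolved_orientation())
    ref = ds.labels.astype(float)
    if cfg.normalize_reference:
        ref = min_max_normalize(ref)

    s = grey_coefficients(ref, X, cfg)
    alpha, cr = ahp_weights(Q)
    beta = critic_weights(X)
    omega = combine_weights(alpha, beta)
    degree = weighted_degree(s, omega)
    order = np.argsort(-degree, kind="stable")
    ranking = tuple(ds.indicator_names[i] for i in order)
    return RelationalResult(
        coefficients=s,
        alpha=alpha,
        beta=beta,
        omega=omega,
        degree=degree,
        ranking=ranking,
        consistency_ratio=cr,
        indicator_names=tuple(ds.indicator_names),
    )


@dataclass
class FeatureSelection:
    selected: tuple[str, ...]
    result: RelationalResult


def select_features(
    ds: Dataset,
    q: int = 4,
    Q: ComparisonMatrix | None = None,
    cfg: GreyConfig | None = None,
) -> FeatureSelection:
    """Select the top-q indicators by weighted relational degree."""
    if not 1 <= q <= ds.n:
        raise ConfigError(f"q must be in 1..{ds.n}, got {q}")
    res = relational_analysis(ds, Q=Q, cfg=cfg)
    return FeatureSelection(selected=res.ranking[:q], result=res)
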