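"""GB3838-2002 surface-water class limits and single-factor classification.

The Chinese surface-water environmental quality standard defines five graded
classes (I best .. V worst) with per-class limits for a subset of indicators;
samples failing the class-V limit of any indicator fall into a sixth category,
"poor V".  Only dissolved oxygen (lower limits), ammonia nitrogen, permanganate
index and total dissolved solids (upper limits) carry per-class bands.
Turbidity and pH have single advisory limits (drinking-water turbidity
1 NTU, pH 6-9) and therefore cannot map to a class; they are exposed as
pass/fail flags.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .errors import ValidationError

#: Ordinal class encoding: I -> 1 ... V -> 5, poor V -> 6.
CLASS_NAMES: dict[int, str] = {1: "I", 2: "II", 3: "III", 4: "IV", 5: "V", 6: "poor V"}
NAME_TO_CLASS: dict[str, int] = {v: k for k, v in CLASS_NAMES.items()}

#: Indicators with per-class limits (the "limited" indicators).
LIMITED_INDICATORS = ("do", "nh3n", "codmn", "tds")


@dataclass(frozen=True)
class ClassStandard:
    """Per-class limits for the limited indicators plus advisory limits.

    ``do_min`` are lower limits (water must have at least this much dissolved
    oxygen, mg/L, to attain the class); the other tuples are upper limits.
    Index 0 corresponds to class I, index 4 to class V.
    """

    do_min: tuple[float, float, float, float, float] = (7.5, 6.0, 5.0, 3.0, 1.0)
    nh3n_max: tuple[float, float, float, float, float] = (0.15, 0.5, 1.0, 1.5, 2.0)
    codmn_max: tuple[float, float, float, float, float] = (2.0, 4.0, 6.0, 10.0, 15.0)
    tds_max: tuple[float, float, float, float, float] = (150.0, 300.0, 450.0, 550.0, 550.0)
    turbidity_max: float = 1.0
    ph_range: tuple[float, float] = (6.0, 9.0)

    def __post_init__(self) -> None:
        for name, limits, increasing in (
            ("do_min", self.do_min, False),
            ("nh3n_max", self.nh3n_max, True),
            ("codmn_max", self.codmn_max, True),
            ("tds_max", self.tds_max, True),
        ):
            if len(limits) != 5:
                raise ValidationError(f"{name}: exactly five class limits required")
            pairs = zip(limits, limits[1:])
            ok = all(a <= b for a, b in pairs) if increasing else all(
                a >= b for a, b in zip(limits, limits[1:])
            )
            if not ok:
                raise ValidationError(f"{name}: limits must be monotone across classes I..V")

    def upper_limits(self, indicator: str) -> tuple[float, ...]:
        return {"nh3n": self.nh3n_max, "codmn": self.codmn_max, "tds": self.tds_max}[indicator]


#: The standard's limits as published.
GB3838 = ClassStandard()


def _class_from_upper(value: float, limits: tuple[float, ...]) -> int:
    """Best (lowest) class whose upper limit the value satisfies; 6 beyond V."""
    for c, lim in enumerate(limits, start=1):
        if value <= lim:
            return c
    return 6


def _class_from_lower(value: float, limits: tuple[float, ...]) -> int:
    """Best (lowest) class whose lower limit the value satisfies; 6 below V."""
    for c, lim in enumerate(limits, start=1):
        if value >= lim:
            return c
    return 6


def indicator_class(indicator: str, value: float, std: ClassStandard = GB3838) -> int:
    """Class 1..6 attained by a single limited indicator value."""
    if not math.isfinite(value):
        raise ValidationError(f"{indicator}: value must be finite, got {value!r}")
    if indicator == "do":
        return _class_from_lower(value, std.do_min)
    if indicator in ("nh3n", "codmn", "tds"):
        return _class_from_upper(value, std.upper_limits(indicator))
    raise ValidationError(f"{indicator!r} has no per-class limits")


def classify_by_standard(sample: Mapping[str, float], std: ClassStandard = GB3838) -> int:
    """Single-factor assessment: the sample's class is its worst indicator class.

    ``sample`` must provide the four limited indicators (``do``, ``nh3n``,
    ``codmn``, ``tds``).  Turbidity and pH never influence the class; see
    :func:`advisory_flags`.
    """
    return max(indicator_class(k, float(sample[k]), std) for k in LIMITED_INDICATORS)


def advisory_flags(sample: Mapping[str, float], std: ClassStandard = GB3838) -> dict[str, bool]:
    """Pass/fail flags for the indicators without class bands."""
    flags: dict[str, bool] = {}
    if "turbidity" in sample:
        flags["turbidity_ok"] = float(sample["turbidity"]) <= std.turbidity_max
    if "ph" in sample:
        lo, hi = std.ph_range
        flags["ph_ok"] = lo <= float(sample["ph"]) <= hi
    return flags
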