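"""Summary arithmetic for group comparisons.

Per-group mean +/- SEM, percent reduction, fold change, and
percent-of-control normalization for axon segment counts. Rounding is
half-away-from-zero at the printed precision so derived figures reproduce
their printed inputs exactly.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "GroupSummary",
    "DerivedComparison",
    "round_half_away",
    "summarize_group",
    "percent_reduction",
    "fold_change",
    "percent_of_control",
    "comparison_table",
]


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean: float
    sem: float


@dataclass(frozen=True)
class DerivedComparison:
    comparison: str
    control_mean: float
    treated_mean: float
    percent_reduction: float
    fold_change: float
    decimals: int


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero at the given number of decimals."""
    f = 10.0**decimals
    return math.copysign(math.floor(abs(x) * f + 0.5), x) / f


def summarize_group(values: Iterable[float], group: str = "") -> GroupSummary:
    """Mean and SEM (sample SD with n-1 denominator over sqrt(n))."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty group")
    if not np.isfinite(arr).all():
        raise ValueError("group values must be finite")
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
    return GroupSummary(group=group, n=int(arr.size), mean=mean, sem=sem)


def _check_control(control_mean: float) -> None:
    if not control_mean > 0:
        raise ValueError("control mean must be positive")


def percent_reduction(
    control_mean: float, treated_mean: float, decimals: Optional[int] = 1
) -> float:
    """(control - treated) / control x 100, rounded half-away-from-zero.

    ``decimals=None`` skips rounding.
    """
    _check_control(control_mean)
    value = (control_mean - treated_mean) / control_mean * 100.0
    return value if decimals is None else round_half_away(value, decimals)


def fold_change(
    control_mean: float, treated_mean: float, decimals: Optional[int] = 1
) -> float:
    """treated / control, rounded half-away-from-zero; ``decimals=None``
    skips rounding."""
    _check_control(control_mean)
    value = treated_mean / control_mean
    return value if decimals is None else round_half_away(value, decimals)


def percent_of_control(
    segment_counts: Iterable[float], control_segment_counts: Iterable[float]
) -> float:
    """Mean treated over mean control, as a percentage.

    Used to normalize per-segment axon counts (50 x 50 um^2 segments) to a
    control group.
    """
    treated = np.asarray(list(segment_counts), dtype=float)
    control = np.asarray(list(control_segment_counts), dtype=float)
    if treated.size == 0 or control.size == 0:
        raise ValueError("segment count lists must be non-empty")
    _check_control(float(control.mean()))
    return float(treated.mean() / control.mean() * 100.0)


def comparison_table(comparisons: Iterable[dict]) -> pd.DataFrame:
    """Tidy table of derived comparisons from printed group means.

    Each input dict needs: comparison, control_mean, treated_mean, and
    optionally decimals (default 1).
    """
    rows = []
    for c in comparisons:
        d = int(c.get("decimals", 1))
        rows.append(
            DerivedComparison(
                comparison=str(c["comparison"]),
                control_mean=float(c["control_mean"]),
                treated_mean=float(c["treated_mean"]),
                percent_reduction=percent_reduction(c["control_mean"], c["treated_mean"], d),
                fold_change=fold_change(c["control_mean"], c["treated_mean"], d),
                decimals=d,
            ).__dict__
        )
    return pd.DataFrame(rows)
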