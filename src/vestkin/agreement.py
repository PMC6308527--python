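"""Method-agreement statistics for IMU vs motion-capture validation.

Implements the agreement protocol used to validate wearable-sensor metrics
against an optical criterion: intraclass correlation ICC(A,1) — two-way
random effects, absolute agreement, single measure (McGraw & Wong
nomenclature) — root-mean-square error, signed percent error, Bland-Altman
bias and 95% limits of agreement, and the qualitative ICC interpretation of
Koo & Li (poor < 0.5, moderate 0.5-0.75, good 0.75-0.9, excellent > 0.9).

The criterion device (motion capture) is always device A and the test device
(IMU) device B: differences, percent errors and bias are B − A, so a
negative value means the IMU underestimates the criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "PairedMeasurements",
    "AgreementReport",
    "icc_a1",
    "icc_consistency",
    "interpret_icc",
    "rmse",
    "percent_error",
    "bland_altman",
    "agreement_report",
    "aggregate_conditions",
    "round_half_away",
    "UndefinedICCError",
]


class UndefinedICCError(ValueError):
    """ICC is undefined (no between-unit variance to correlate)."""


@dataclass
class PairedMeasurements:
    """Same metric measured by two devices on the same units.

    ``a`` is the criterion (motion capture), ``b`` the device under test
    (IMU); ``units`` are per-pair identifiers (e.g. subject-trial labels).
    """

    a: np.ndarray
    b: np.ndarray
    units: Optional[List[str]] = None
    metric: str = ""

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ValueError("paired vectors must be 1-D and equally long")
        if len(self.a) < 2:
            raise ValueError("need at least 2 pairs")
        if np.isnan(self.a).any() or np.isnan(self.b).any():
            raise ValueError("paired measurements must not contain missing values")
        if self.units is None:
            self.units = [str(i) for i in range(len(self.a))]

    @property
    def n(self) -> int:
        return len(self.a)


@dataclass
class AgreementReport:
    """Agreement summary for one metric in one condition."""

    icc: float
    icc_category: str
    rmse: float
    percent_error: float
    bias: float
    loa_low: float
    loa_high: float
    n: int
    condition: str = ""
    metric: str = ""
    ba_mean: np.ndarray = field(default_factory=lambda: np.empty(0))
    ba_diff: np.ndarray = field(default_factory=lambda: np.empty(0))


def icc_a1(pairs: PairedMeasurements) -> float:
    """ICC(A,1): two-way random effects, absolute agreement, single measure.

    From the two-way ANOVA mean squares with n units (rows) and k = 2
    devices (columns)::

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    Raises :class:`UndefinedICCError` when the units have no variance (the
    ratio is then 0/0 rather than a meaningful 0).
    """
    x = np.stack([pairs.a, pairs.b], axis=1)  # n units x k raters
    n, k = x.shape
    if n < 3:
        raise ValueError("need at least 3 pairs for a two-way ANOVA")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if ss_total < 1e-300 or ss_rows <= 1e-12 * ss_total:
        raise UndefinedICCError("no between-unit variance: ICC(A,1) is undefined")
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    value = (msr - mse) / denom
    if value < 0:
        warnings.warn(f"negative ICC(A,1) = {value:.3f}; reported as computed", stacklevel=2)
    return float(value)


def icc_consistency(pairs: PairedMeasurements) -> float:
    """ICC(C,1) (consistency): insensitive to constant device offsets."""
    x = np.stack([pairs.a, pairs.b], axis=1)
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_err = np.sum((x - grand) ** 2) - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if msr < 1e-300 and mse < 1e-300:
        raise UndefinedICCError("no between-unit variance: ICC(C,1) is undefined")
    return float((msr - mse) / (msr + (k - 1) * mse))


def interpret_icc(value: float) -> str:
    """Koo-Li qualitative category for an ICC value.

    Boundary values fall on the lower category as conventionally printed:
    0.5 and 0.75 are 'moderate', 0.9 is 'good'.
    """
    if not -1.0 <= value <= 1.0:
        raise ValueError(f"ICC must lie in [-1, 1], got {value}")
    if value < 0.5:
        return "poor"
    if value <= 0.75:
        return "moderate"
    if value <= 0.9:
        return "good"
    return "excellent"


def rmse(pairs: PairedMeasurements) -> float:
    """Root-mean-square error of the test device against the criterion."""
    return float(np.sqrt(np.mean((pairs.b - pairs.a) ** 2)))


def percent_error(pairs: PairedMeasurements) -> float:
    """Signed mean percent error, 100 (B − A)/A averaged over pairs.

    Signed errors can cancel; a negative result means the IMU underestimates
    on average.  Zero criterion values make the ratio undefined and raise.
    """
    zero = np.flatnonzero(pairs.a == 0)
    if len(zero):
        bad = [pairs.units[i] for i in zero]
        raise ValueError(f"criterion value is zero for units {bad}; percent error undefined")
    return float(np.mean(100.0 * (pairs.b - pairs.a) / pairs.a))


def bland_altman(pairs: PairedMeasurements) -> Tuple[float, float, float, np.ndarray, np.ndarray]:
    """Bland-Altman bias and 95% limits of agreement.

    Returns ``(bias, loa_low, loa_high, pair_means, pair_diffs)`` where the
    limits are bias ± 1.96 x sample SD of the differences and the last two
    arrays are the plot coordinates (mean of the pair, difference B − A).
    """
    d = pairs.b - pairs.a
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return (
        bias,
        bias - 1.96 * sd,
        bias + 1.96 * sd,
        0.5 * (pairs.a + pairs.b),
        d,
    )


def agreement_report(
    pairs: PairedMeasurements, condition: str = "", metric: str = ""
) -> AgreementReport:
    """Full agreement summary (ICC, RMSE, percent error, Bland-Altman)."""
    icc = icc_a1(pairs)
    bias, lo, hi, means, diffs = bland_altman(pairs)
    return AgreementReport(
        icc=icc,
        icc_category=interpret_icc(icc) if -1 <= icc <= 1 else "poor",
        rmse=rmse(pairs),
        percent_error=percent_error(pairs),
        bias=bias,
        loa_low=lo,
        loa_high=hi,
        n=pairs.n,
        condition=condition,
        metric=metric,
        ba_mean=means,
        ba_diff=diffs,
    )


def round_half_away(x: float, decimals: int) -> float:
    """Round half away from zero (the convention of printed clinical tables)."""
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def aggregate_conditions(per_condition: pd.DataFrame, decimals=None) -> pd.DataFrame:
    """Append 'Mean across conditions' and 'SD across conditions' rows.

    ``per_condition`` must have exactly 8 rows (the task battery) and numeric
    columns; the appended rows are the column mean and the sample SD (n−1
    denominator).  ``decimals`` may map column names to printed precision;
    those columns are then rounded half-away-from-zero for display while the
    computation itself uses full precision.
    """
    if len(per_condition) != 8:
        raise ValueError(f"expected 8 condition rows, got {len(per_condition)}")
    num = per_condition.select_dtypes(include=[np.number])
    mean_row = num.mean(axis=0)
    sd_row = num.std(axis=0, ddof=1)
    out = per_condition.copy()
    out.loc["Mean across conditions"] = mean_row
    out.loc["SD across conditions"] = sd_row
    if decimals:
        for col, dec in decimals.items():
            if col in out.columns:
                out[col] = [
                    round_half_away(v, dec) if np.isfinite(v) else v for v in out[col]
                ]
    return out
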