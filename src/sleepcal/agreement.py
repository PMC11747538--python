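"""Inter-device agreement statistics.

Implements the single-measurement intraclass correlation coefficients from
the two-way crossed ANOVA decomposition without replication:

* **consistency** (two-way mixed effects, consistency, single measurement)::

      ICC(C,1) = (MSR - MSE) / (MSR + (k - 1) MSE)

* **absolute agreement** (two-way mixed effects, absolute agreement,
  single measurement)::

      ICC(A,1) = (MSR - MSE) / (MSR + (k - 1) MSE + (k / n)(MSC - MSE))

where MSR, MSC and MSE are the between-row (nights), between-column
(devices) and residual mean squares.  Confidence intervals follow the
standard F-quantile construction: exact F bounds for the consistency form
and the Satterthwaite-approximated F interval for the absolute form (the
convention of the McGraw & Wong formulation implemented by the usual ICC
packages; the absolute lower bound can be negative).

Bland-Altman difference summaries use the project-wide sign convention
``test - ref`` (negative = the test device underestimates).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "RatingsMatrix",
    "AnovaSquares",
    "ICCResult",
    "DifferenceSummary",
    "two_way_mean_squares",
    "icc_single",
    "bland_altman_stats",
    "classify_icc",
]


@dataclass
class RatingsMatrix:
    """An n x k grid of measurements: rows are nights (pooled across
    participants), columns are devices."""

    values: np.ndarray
    row_labels: Sequence[tuple[str, str]] | None = None
    col_labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ratings must be a 2-D array")
        n, k = self.values.shape
        if n < 3:
            raise ValueError(f"need at least 3 rows for mean squares, got {n}")
        if k < 2:
            raise ValueError(f"need at least 2 columns, got {k}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ratings contain missing or non-finite cells")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class AnovaSquares:
    """Mean squares of the two-way crossed decomposition (no replication)."""

    ms_rows: float
    ms_cols: float
    ms_err: float
    n: int
    k: int


@dataclass(frozen=True)
class ICCResult:
    form: str  # "absolute" | "consistency"
    estimate: float
    ci_low: float
    ci_high: float
    conf_level: float
    n: int
    k: int


@dataclass(frozen=True)
class DifferenceSummary:
    """Bland-Altman summary of per-night differences (test - ref), hours."""

    mean_diff: float
    sd_diff: float
    max_diff: float
    min_diff: float
    loa_low: float
    loa_high: float
    n: int


def two_way_mean_squares(m: RatingsMatrix) -> AnovaSquares:
    """Row, column and residual mean squares of the n x k grid."""
    x = m.values
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ss_err = float(np.sum(resid**2))
    return AnovaSquares(
        ms_rows=ss_rows / (n - 1),
        ms_cols=ss_cols / (k - 1),
        ms_err=ss_err / ((n - 1) * (k - 1)),
        n=n,
        k=k,
    )


def _consistency_ci(sq: AnovaSquares, alpha: float) -> tuple[float, float]:
    n, k = sq.n, sq.k
    df1, df2 = n - 1, (n - 1) * (k - 1)
    if sq.ms_err == 0.0:
        return 1.0, 1.0
    f_obs = sq.ms_rows / sq.ms_err
    fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
    fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
    return (fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1)


def _absolute_ci(sq: AnovaSquares, est: float, alpha: float) -> tuple[float, float]:
    n, k = sq.n, sq.k
    msr, msc, mse = sq.ms_rows, sq.ms_cols, sq.ms_err
    if est >= 1.0:
        return 1.0, 1.0
    # Satterthwaite degrees of freedom for the denominator combination
    a = k * est / (n * (1 - est))
    b = 1 + k * est * (n - 1) / (n * (1 - est))
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num / den if den > 0 else np.inf
    f_low = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_up = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = (
        n * (msr - f_low * mse)
        / (f_low * (k * msc + (k * n - k - n) * mse) + n * msr)
    )
    upper = (
        n * (f_up * msr - mse)
        / (k * msc + (k * n - k - n) * mse + n * f_up * msr)
    )
    return lower, upper


def icc_single(
    m: RatingsMatrix, form: str = "absolute", conf_level: float = 0.95
) -> ICCResult:
    """Single-measurement ICC with a two-sided confidence interval.

    Parameters
    ----------
    form
        ``"absolute"`` penalizes systematic between-device offsets;
        ``"consistency"`` does not.
    """
    if form not in ("absolute", "consistency"):
        raise ValueError(f"unknown ICC form {form!r}")
    if not 0 < conf_level < 1:
        raise ValueError("conf_level must be in (0, 1)")
    sq = two_way_mean_squares(m)
    n, k = sq.n, sq.k
    alpha = 1 - conf_level

    if form == "consistency":
        denom = sq.ms_rows + (k - 1) * sq.ms_err
        if denom == 0.0:
            raise ZeroDivisionError("degenerate ratings: ICC undefined")
        est = (sq.ms_rows - sq.ms_err) / denom
        lo, hi = _consistency_ci(sq, alpha)
    else:
        denom = (
            sq.ms_rows
            + (k - 1) * sq.ms_err
            + (k / n) * (sq.ms_cols - sq.ms_err)
        )
        if denom == 0.0:
            raise ZeroDivisionError("degenerate ratings: ICC undefined")
        est = (sq.ms_rows - sq.ms_err) / denom
        lo, hi = _absolute_ci(sq, est, alpha)

    return ICCResult(
        form=form,
        estimate=float(est),
        ci_low=float(min(lo, est)),
        ci_high=float(max(hi, est)),
        conf_level=conf_level,
        n=n,
        k=k,
    )


def bland_altman_stats(
    pairs: Iterable[tuple[float, float]] | np.ndarray,
) -> DifferenceSummary:
    """Difference summary over paired (test, ref) measurements.

    Differences are ``test - ref``; limits of agreement are
    mean ± 1.96 x SD (SD with n-1 denominator).
    """
    arr = np.asarray(list(pairs) if not isinstance(pairs, np.ndarray) else pairs,
                     dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 (test, ref) pairs")
    d = arr[:, 0] - arr[:, 1]
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return DifferenceSummary(
        mean_diff=mean,
        sd_diff=sd,
        max_diff=float(d.max()),
        min_diff=float(d.min()),
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
        n=int(d.size),
    )


def classify_icc(estimate: float) -> str:
    """Qualitative reliability label for an ICC point estimate.

    Bands: < 0.5 poor, 0.5-0.75 moderate, 0.75-0.9 good, >= 0.9 excellent.
    """
    if estimate > 1.0:
        raise ValueError(f"ICC estimate cannot exceed 1, got {estimate}")
    if estimate < 0.5:
        return "poor"
    if estimate < 0.75:
        return "moderate"
    if estimate < 0.9:
        return "good"
    return "excellent"
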