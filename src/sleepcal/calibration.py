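"""Two-stage linear calibration of test-device sleep measurements.

The test device (e.g. a minute-resolution activity watch) systematically
overestimates sleep onset latency and underestimates total sleep time
relative to the reference actigraph.  Calibration proceeds in two stages:

1. **Sleep duration.**  OLS regresses the reference onset latency on the
   test latency, ``L_hat = alpha * S + beta``.  The measured duration is
   corrected by the latency overestimate, ``D* = D + (S - L_hat)``, and a
   small bias term ``b`` (|b| <= 5 min), selected by grid search to
   maximize the absolute-agreement ICC against the reference duration,
   absorbs residual offset-latency bias.  The calibrated duration is
   clipped to the physical bound::

       D' = min{ c * S + D + d, TIB },  c = 1 - alpha,  d = -beta + b*

2. **TST.**  OLS regresses reference TST on test TST directly, and the
   result is clipped to the calibrated duration::

       T' = min{ m * T + t0, D' }

The package's default model carries the published coefficients for the
iAide2-to-MW8 correction, ``D' = min{0.59 S + D + 0.26, TIB}`` and
``T' = min{0.73 T + 2.15, D'}`` (hours).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .agreement import RatingsMatrix, icc_single
from .metrics import PairedNight, SleepMetrics

__all__ = [
    "CalibrationModel",
    "BiasGrid",
    "default_calibration",
    "fit_duration_calibration",
    "fit_tst_calibration",
    "fit_calibration",
    "apply_duration_calibration",
    "apply_tst_calibration",
    "apply_calibration",
]

#: Default coefficients of the published iAide2 -> MW8 calibration (hours).
DEFAULT_DUR_LATENCY_COEF = 0.59
DEFAULT_DUR_INTERCEPT = 0.26
DEFAULT_TST_SLOPE = 0.73
DEFAULT_TST_INTERCEPT = 2.15


@dataclass(frozen=True)
class BiasGrid:
    """Symmetric grid of candidate bias terms for the duration stage.

    Bounds and step in minutes; default is +/-5 min in 0.1 min steps.
    """

    low_min: float = -5.0
    high_min: float = 5.0
    step_min: float = 0.1

    def candidates_hours(self) -> np.ndarray:
        if self.step_min <= 0 or self.high_min < self.low_min:
            raise ValueError("invalid bias grid")
        n = int(round((self.high_min - self.low_min) / self.step_min))
        # integer stepping avoids floating-point drift across the grid
        return (self.low_min + self.step_min * np.arange(n + 1)) / 60.0


@dataclass(frozen=True)
class CalibrationModel:
    """Coefficients of the two-stage correction, with provenance.

    ``duration_cal = min{dur_latency_coef * S + D + dur_intercept, TIB}``;
    ``tst_cal = min{tst_slope * T + tst_intercept, duration_cal}``.
    """

    dur_latency_coef: float = DEFAULT_DUR_LATENCY_COEF
    dur_intercept: float = DEFAULT_DUR_INTERCEPT
    tst_slope: float = DEFAULT_TST_SLOPE
    tst_intercept: float = DEFAULT_TST_INTERCEPT
    provenance: str = "default"  # "default" | "fitted"
    fit_diagnostics: Optional[dict] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.provenance == "fitted" and not 0 <= self.dur_latency_coef <= 1:
            raise ValueError(
                "fitted dur_latency_coef outside [0, 1]: the latency "
                f"correction cannot exceed the latency itself ({self.dur_latency_coef})"
            )


def default_calibration() -> CalibrationModel:
    """The published default coefficients (0.59, 0.26, 0.73, 2.15)."""
    return CalibrationModel(provenance="default")


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and intercept of y on x."""
    if np.ptp(x) == 0:
        raise ValueError("degenerate regressor: all values equal")
    A = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(slope), float(intercept)


def _as_arrays(cohort: Sequence[PairedNight]):
    S = np.array([p.metrics_test.onset_latency for p in cohort])
    D = np.array([p.metrics_test.duration for p in cohort])
    T = np.array([p.metrics_test.tst for p in cohort])
    TIB = np.array([p.metrics_test.tib for p in cohort])
    L_ref = np.array([p.metrics_ref.onset_latency for p in cohort])
    D_ref = np.array([p.metrics_ref.duration for p in cohort])
    T_ref = np.array([p.metrics_ref.tst for p in cohort])
    return S, D, T, TIB, L_ref, D_ref, T_ref


def fit_duration_calibration(
    cohort: Sequence[PairedNight],
    bias_grid: BiasGrid | None = None,
) -> CalibrationModel:
    """Fit the duration stage (latency OLS + ICC-optimizing bias term).

    The returned model's TST stage is the identity (slope 1, intercept 0)
    until :func:`fit_tst_calibration` fills it in.
    """
    if len(cohort) < 3:
        raise ValueError("need at least 3 paired nights to fit")
    bias_grid = bias_grid or BiasGrid()
    S, D, _, TIB, L_ref, D_ref, _ = _as_arrays(cohort)

    alpha_raw, beta = _ols(S, L_ref)
    # constrain the slope to [0, 1]: the latency correction can neither be
    # negative nor exceed the measured latency itself; when the unconstrained
    # OLS slope falls outside (noisy, heavily clipped latencies), keep the
    # least-squares intercept for the clamped slope
    alpha = float(np.clip(alpha_raw, 0.0, 1.0))
    if alpha != alpha_raw:
        beta = float(np.mean(L_ref) - alpha * np.mean(S))
    d_star = D + (S - (alpha * S + beta))  # = D + (1 - alpha) S - beta

    best_b = None
    best_icc = -np.inf
    for b in bias_grid.candidates_hours():
        cal = np.minimum(d_star + b, TIB)
        try:
            icc = icc_single(
                RatingsMatrix(np.column_stack([cal, D_ref])), "absolute"
            ).estimate
        except (ValueError, ZeroDivisionError):
            continue  # degenerate candidate
        # ties broken toward smallest |b|, then negative b
        if icc > best_icc + 1e-12 or (
            abs(icc - best_icc) <= 1e-12
            and best_b is not None
            and (abs(b), b >= 0) < (abs(best_b), best_b >= 0)
        ):
            best_icc, best_b = icc, float(b)
    if best_b is None:
        raise ValueError("ICC undefined for every bias candidate")

    coef = float(np.clip(1.0 - alpha, 0.0, 1.0))  # guard fp round-off at the bounds
    resid = np.minimum(d_star + best_b, TIB) - D_ref
    return CalibrationModel(
        dur_latency_coef=coef,
        dur_intercept=-beta + best_b,
        tst_slope=1.0,
        tst_intercept=0.0,
        provenance="fitted",
        fit_diagnostics={
            "latency_ols_slope": alpha,
            "latency_ols_slope_unconstrained": alpha_raw,
            "latency_ols_intercept": beta,
            "bias_term_h": best_b,
            "bias_icc": best_icc,
            "duration_rmse_h": float(np.sqrt(np.mean(resid**2))),
            "n_nights": len(cohort),
        },
    )


def apply_duration_calibration(model: CalibrationModel, m: SleepMetrics) -> float:
    """Calibrated sleep duration, clipped so it never exceeds TIB."""
    return float(
        min(model.dur_latency_coef * m.onset_latency + m.duration + model.dur_intercept,
            m.tib)
    )


def fit_tst_calibration(
    cohort: Sequence[PairedNight],
    calibrated_durations: Sequence[float] | None = None,
    base_model: CalibrationModel | None = None,
) -> CalibrationModel:
    """Fit the TST stage by OLS of reference TST on test TST.

    ``calibrated_durations`` (one per night, same order) is accepted for
    interface symmetry and diagnostics; the OLS itself uses all nights.
    If ``base_model`` is given, its duration stage is kept.
    """
    if len(cohort) < 3:
        raise ValueError("need at least 3 paired nights to fit")
    _, _, T, _, _, _, T_ref = _as_arrays(cohort)
    slope, intercept = _ols(T, T_ref)
    resid = slope * T + intercept - T_ref
    diag = dict(base_model.fit_diagnostics or {}) if base_model else {}
    diag.update(
        tst_ols_slope=slope,
        tst_ols_intercept=intercept,
        tst_rmse_h=float(np.sqrt(np.mean(resid**2))),
    )
    base = base_model or CalibrationModel(
        dur_latency_coef=0.0, dur_intercept=0.0, provenance="fitted"
    )
    return replace(
        base,
        tst_slope=slope,
        tst_intercept=intercept,
        provenance="fitted",
        fit_diagnostics=diag,
    )


def apply_tst_calibration(
    model: CalibrationModel, m: SleepMetrics, d_prime: float
) -> float:
    """Calibrated TST, clipped to the same night's calibrated duration and
    floored at zero (the floor only matters for pathological models)."""
    return float(max(min(model.tst_slope * m.tst + model.tst_intercept, d_prime), 0.0))


def fit_calibration(
    cohort: Sequence[PairedNight],
    bias_grid: BiasGrid | None = None,
) -> CalibrationModel:
    """Fit both stages: duration first, then TST (whose clip bound is the
    calibrated duration)."""
    dur_model = fit_duration_calibration(cohort, bias_grid)
    d_prime = [apply_duration_calibration(dur_model, p.metrics_test) for p in cohort]
    return fit_tst_calibration(cohort, d_prime, base_model=dur_model)


def apply_calibration(
    model: CalibrationModel, cohort: Iterable[PairedNight]
) -> list[tuple[float, float]]:
    """Per-night (calibrated duration, calibrated TST) for the test device."""
    out = []
    for p in cohort:
        d_prime = apply_duration_calibration(model, p.metrics_test)
        out.append((d_prime, apply_tst_calibration(model, p.metrics_test, d_prime)))
    return out
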