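"""Leave-one-participant-out robustness of calibrated agreement.

For each participant, their nights are dropped and the absolute-agreement
ICC of calibrated duration and TST against the reference is recomputed on
the remaining nights, either applying the full-cohort calibration
(``fixed`` mode) or refitting the calibration on the subset (``refit``
mode).  Small ranges across exclusions indicate that neither the
agreement estimates nor the calibration hinge on any one participant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .agreement import RatingsMatrix, icc_single
from .calibration import (
    BiasGrid,
    CalibrationModel,
    apply_calibration,
    fit_calibration,
)
from .metrics import PairedNight

__all__ = ["LOOEntry", "SensitivityResult", "leave_one_out"]


@dataclass(frozen=True)
class LOOEntry:
    icc_duration: Optional[float]
    icc_tst: Optional[float]
    n_nights: int
    valid: bool = True
    message: str = ""


@dataclass(frozen=True)
class SensitivityResult:
    mode: str  # "fixed" | "refit"
    per_excluded: dict[str, LOOEntry]
    range_duration: tuple[float, float]
    range_tst: tuple[float, float]


def _calibrated_iccs(
    subset: Sequence[PairedNight], model: CalibrationModel
) -> tuple[float, float]:
    cal = np.asarray(apply_calibration(model, subset))
    d_ref = np.array([p.metrics_ref.duration for p in subset])
    t_ref = np.array([p.metrics_ref.tst for p in subset])
    icc_d = icc_single(RatingsMatrix(np.column_stack([cal[:, 0], d_ref])), "absolute")
    icc_t = icc_single(RatingsMatrix(np.column_stack([cal[:, 1], t_ref])), "absolute")
    return icc_d.estimate, icc_t.estimate


def leave_one_out(
    cohort: Sequence[PairedNight],
    mode: str = "fixed",
    full_model: Optional[CalibrationModel] = None,
    bias_grid: Optional[BiasGrid] = None,
) -> SensitivityResult:
    """Leave-one-participant-out ICCs for calibrated duration and TST.

    Parameters
    ----------
    mode
        ``"fixed"`` applies ``full_model`` (fitted on everyone, or the
        package default) to each subset; ``"refit"`` refits the
        calibration on each subset.

    Deterministic: no randomness is used.  Subsets too small to fit or to
    form an ICC are recorded as invalid entries and excluded from the
    ranges, never silently dropped.
    """
    if mode not in ("fixed", "refit"):
        raise ValueError(f"mode must be 'fixed' or 'refit', got {mode!r}")
    participants = sorted({p.participant_id for p in cohort})
    if len(participants) < 3:
        raise ValueError(
            f"leave-one-out needs >= 3 participants, got {len(participants)}"
        )
    if mode == "fixed":
        if full_model is None:
            full_model = fit_calibration(cohort, bias_grid)
    per: dict[str, LOOEntry] = {}
    for pid in participants:
        subset = [p for p in cohort if p.participant_id != pid]
        try:
            model = full_model if mode == "fixed" else fit_calibration(subset, bias_grid)
            icc_d, icc_t = _calibrated_iccs(subset, model)
        except (ValueError, ZeroDivisionError) as err:
            per[pid] = LOOEntry(None, None, len(subset), valid=False, message=str(err))
            continue
        per[pid] = LOOEntry(icc_d, icc_t, len(subset))

    valid = [e for e in per.values() if e.valid]
    if not valid:
        raise ValueError("every leave-one-out subset was degenerate")
    d_vals = [e.icc_duration for e in valid]
    t_vals = [e.icc_tst for e in valid]
    return SensitivityResult(
        mode=mode,
        per_excluded=per,
        range_duration=(min(d_vals), max(d_vals)),
        range_tst=(min(t_vals), max(t_vals)),
    )
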