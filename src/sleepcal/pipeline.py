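"""End-to-end orchestration: simulate/read -> metrics -> agreement ->
calibration -> calibrated agreement -> leave-one-out sensitivity.

A run writes a self-contained set of artifacts to an output directory
(CSV inputs/metrics, JSON summaries, a fitted model, a human-readable
``report.md`` and ``run.log``), each stamped with the run's seed and a
hash of the configuration.  Reruns with the same configuration are
byte-identical except for timestamps in the log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import io as sio
from .agreement import RatingsMatrix, bland_altman_stats, classify_icc, icc_single
from .calibration import (
    BiasGrid,
    CalibrationModel,
    apply_calibration,
    default_calibration,
    fit_calibration,
)
from .cohort import CohortConfig, generate_cohort
from .metrics import PairedNight, derive_cohort_metrics
from .sensitivity import leave_one_out

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger("sleepcal")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``cohort`` (generator config) or both CSV input paths
    must be provided.
    """

    cohort: Optional[CohortConfig] = None
    epochs_path: Optional[str] = None
    markers_path: Optional[str] = None
    outdir: str = "sleepcal_run"
    conf_level: float = 0.95
    bias_grid: BiasGrid = field(default_factory=BiasGrid)
    use_default_calibration: bool = False
    run_sensitivity: bool = True
    make_plots: bool = False
    seed: Optional[int] = None  # overrides cohort.seed when generating

    def __post_init__(self) -> None:
        have_csv = self.epochs_path is not None and self.markers_path is not None
        if (self.cohort is None) == (not have_csv):
            raise ValueError("provide either a generator config or input CSV paths")

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("outdir", None)  # identify the analysis, not its destination
        payload.pop("make_plots", None)
        digest = hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()
        return digest[:12]


def _measure_summary(
    pairs: np.ndarray, conf_level: float
) -> dict:
    m = RatingsMatrix(pairs)
    icc_abs = icc_single(m, "absolute", conf_level)
    icc_con = icc_single(m, "consistency", conf_level)
    return {
        "icc_absolute": icc_abs,
        "icc_absolute_label": classify_icc(icc_abs.estimate),
        "icc_consistency": icc_con,
        "icc_consistency_label": classify_icc(icc_con.estimate),
        "bland_altman": bland_altman_stats(pairs),
    }


def agreement_summary(
    paired: Sequence[PairedNight],
    conf_level: float = 0.95,
    calibrated: Optional[np.ndarray] = None,
) -> dict:
    """ICC (both forms) + Bland-Altman for duration and TST.

    If ``calibrated`` (n x 2 array of calibrated duration, TST) is given,
    the test-device columns are replaced by the calibrated values.
    """
    d_test = np.array([p.metrics_test.duration for p in paired])
    t_test = np.array([p.metrics_test.tst for p in paired])
    if calibrated is not None:
        d_test, t_test = calibrated[:, 0], calibrated[:, 1]
    d_ref = np.array([p.metrics_ref.duration for p in paired])
    t_ref = np.array([p.metrics_ref.tst for p in paired])
    return {
        "n_nights": len(paired),
        "duration": _measure_summary(np.column_stack([d_test, d_ref]), conf_level),
        "tst": _measure_summary(np.column_stack([t_test, t_ref]), conf_level),
    }


def _fmt_icc(entry: dict, key: str) -> str:
    r = entry[key]
    return (
        f"{r.estimate:.2f} (95% CI {r.ci_low:.2f} to {r.ci_high:.2f}; "
        f"{entry[key + '_label']})"
    )


def _report(run: RunConfig, uncal: dict, cal: dict, model: CalibrationModel,
            sens: dict, n_flags: int) -> str:
    lines = [
        "# Dual-device sleep agreement report",
        "",
        f"- config hash: `{run.config_hash()}`",
        f"- nights analyzed: {uncal['n_nights']} (QC-excluded: {n_flags})",
        "",
        "## Measurements (uncalibrated)",
        "",
        "| measure | ICC absolute | ICC consistency | mean diff (h) | min / max diff (h) |",
        "|---|---|---|---|---|",
    ]
    for name in ("duration", "tst"):
        e = uncal[name]
        ba = e["bland_altman"]
        lines.append(
            f"| {name} | {_fmt_icc(e, 'icc_absolute')} | {_fmt_icc(e, 'icc_consistency')} "
            f"| {ba.mean_diff:.2f} | {ba.min_diff:.2f} / {ba.max_diff:.2f} |"
        )
    lines += [
        "",
        "## Calibration",
        "",
        f"- provenance: {model.provenance}",
        f"- duration: D' = min{{{model.dur_latency_coef:.2f} S + D + "
        f"{model.dur_intercept:.2f}, TIB}} (hours)",
        f"- TST: T' = min{{{model.tst_slope:.2f} T + {model.tst_intercept:.2f}, D'}} (hours)",
        "",
        "| measure | ICC absolute (calibrated) | mean diff (h) | min / max diff (h) |",
        "|---|---|---|---|",
    ]
    for name in ("duration", "tst"):
        e = cal[name]
        ba = e["bland_altman"]
        lines.append(
            f"| {name} | {_fmt_icc(e, 'icc_absolute')} | {ba.mean_diff:.2f} "
            f"| {ba.min_diff:.2f} / {ba.max_diff:.2f} |"
        )
    lines += ["", "## Sensitivity (leave one participant out)", ""]
    if not sens:
        lines.append("not run (requires >= 3 participants)")
    for mode, res in sens.items():
        lines.append(
            f"- {mode}: duration ICC range "
            f"{res.range_duration[0]:.2f}-{res.range_duration[1]:.2f}, "
            f"TST ICC range {res.range_tst[0]:.2f}-{res.range_tst[1]:.2f}"
        )
    lines.append("")
    return "\n".join(lines)


def _plots(outdir: Path, paired, cal_values) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    d_ref = np.array([p.metrics_ref.duration for p in paired])
    t_ref = np.array([p.metrics_ref.tst for p in paired])
    panels = {
        "duration_uncal": (np.array([p.metrics_test.duration for p in paired]), d_ref),
        "tst_uncal": (np.array([p.metrics_test.tst for p in paired]), t_ref),
        "duration_cal": (cal_values[:, 0], d_ref),
        "tst_cal": (cal_values[:, 1], t_ref),
    }
    fig, axes = plt.subplots(len(panels), 2, figsize=(9, 3.2 * len(panels)))
    for ax_row, (name, (test, ref)) in zip(axes, panels.items()):
        ax_row[0].scatter(ref, test, s=12)
        lims = [min(ref.min(), test.min()), max(ref.max(), test.max())]
        ax_row[0].plot(lims, lims, "k--", lw=0.8)
        ax_row[0].set(title=f"{name}: test vs ref", xlabel="ref (h)", ylabel="test (h)")
        d = test - ref
        mean, sd = d.mean(), d.std(ddof=1)
        ax_row[1].scatter((test + ref) / 2, d, s=12)
        for y, style in ((mean, "-"), (mean + 1.96 * sd, ":"), (mean - 1.96 * sd, ":")):
            ax_row[1].axhline(y, color="k", ls=style, lw=0.8)
        ax_row[1].set(title=f"{name}: Bland-Altman", xlabel="mean (h)", ylabel="diff (h)")
    fig.tight_layout()
    fig.savefig(outdir / "plots.png", dpi=120)
    plt.close(fig)


def run_pipeline(run: RunConfig) -> dict:
    """Execute the full analysis; returns the in-memory results dict and
    writes all artifacts under ``run.outdir``.

    Raises :class:`PipelineError` (removing partial artifacts) when fewer
    than 3 valid nights survive QC, or when sensitivity is requested with
    fewer than 3 participants.
    """
    outdir = Path(run.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []

    def _write(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        created.append(path)
        return path

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        if run.cohort is not None:
            cohort_cfg = run.cohort
            if run.seed is not None:
                cohort_cfg = dataclasses.replace(cohort_cfg, seed=run.seed)
            log.info("generating cohort (seed=%s)", cohort_cfg.seed)
            records = generate_cohort(cohort_cfg)
            _write("epochs.csv", lambda p: sio.write_cohort_csv(
                records, p, outdir / "markers.csv"))
            created.append(outdir / "markers.csv")
        else:
            log.info("reading cohort from %s / %s", run.epochs_path, run.markers_path)
            records = sio.read_cohort_csv(run.epochs_path, run.markers_path)

        paired, flags = derive_cohort_metrics(records)
        _write("metrics.csv", lambda p: sio.write_metrics_csv(paired, p))
        _write("qc_flags.csv", lambda p: sio.write_qc_csv(flags, p))
        log.info("derived metrics for %d nights (%d flagged)", len(paired), len(flags))
        if len(paired) < 3:
            raise PipelineError(
                f"only {len(paired)} valid nights after QC; need at least 3"
            )

        stamp = {"config_hash": run.config_hash(),
                 "seed": None if run.cohort is None else cohort_cfg.seed}
        uncal = agreement_summary(paired, run.conf_level)
        _write("agreement.json", lambda p: sio.write_json({**stamp, **uncal}, p))

        if run.use_default_calibration:
            model = default_calibration()
        else:
            log.info("fitting calibration")
            model = fit_calibration(paired, run.bias_grid)
        _write("calibration.json", lambda p: sio.model_to_json(model, p))

        cal_values = np.asarray(apply_calibration(model, paired))
        rows = [
            {
                "participant_id": p.participant_id,
                "night_id": p.night_id,
                "duration_cal_h": round(cal_values[i, 0], 4),
                "tst_cal_h": round(cal_values[i, 1], 4),
            }
            for i, p in enumerate(paired)
        ]
        import pandas as pd

        _write("calibrated_metrics.csv",
               lambda p: pd.DataFrame(rows).to_csv(p, index=False))
        cal = agreement_summary(paired, run.conf_level, calibrated=cal_values)
        _write("agreement_calibrated.json",
               lambda p: sio.write_json({**stamp, **cal}, p))

        sens: dict = {}
        n_participants = len({p.participant_id for p in paired})
        if run.run_sensitivity:
            if n_participants < 3:
                raise PipelineError(
                    "sensitivity analysis requires >= 3 participants, "
                    f"got {n_participants}"
                )
            for mode in ("fixed", "refit"):
                sens[mode] = leave_one_out(
                    paired, mode,
                    full_model=model if mode == "fixed" else None,
                    bias_grid=run.bias_grid,
                )
            _write("sensitivity.json", lambda p: sio.write_json({**stamp, **sens}, p))

        if run.make_plots:
            _plots(outdir, paired, cal_values)
            created.append(outdir / "plots.png")

        report = _report(run, uncal, cal, model, sens, len(flags))
        _write("report.md", lambda p: Path(p).write_text(report))
        log.info("run complete: %d artifacts in %s", len(created), outdir)
        return {
            "records": records,
            "paired": paired,
            "qc_flags": flags,
            "uncalibrated": uncal,
            "model": model,
            "calibrated_values": cal_values,
            "calibrated": cal,
            "sensitivity": sens,
        }
    except Exception:
        for path in created:
            path.unlink(missing_ok=True)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
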