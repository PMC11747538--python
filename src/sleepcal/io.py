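"""Readers and writers for the pipeline's on-disk artifacts.

Formats are deliberately plain: epoch series and event markers travel as
CSV with ISO-8601 timestamps, derived metrics as CSV, fitted models and
agreement summaries as JSON, generator/run configuration as YAML.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .agreement import DifferenceSummary, ICCResult
from .calibration import CalibrationModel
from .cohort import CohortConfig
from .metrics import PairedNight, QCFlag
from .records import EpochSeries, NightRecord, VALID_STATES

__all__ = [
    "write_cohort_csv",
    "read_cohort_csv",
    "write_metrics_csv",
    "write_qc_csv",
    "model_to_json",
    "model_from_json",
    "write_json",
    "load_cohort_config",
]

EPOCH_COLUMNS = ["participant_id", "night_id", "device_id", "epoch_start", "epoch_len_s", "state"]
MARKER_COLUMNS = ["participant_id", "night_id", "bedtime", "risetime"]


class SchemaError(ValueError):
    """A CSV input violates the expected schema."""


def write_cohort_csv(
    records: Sequence[NightRecord], epochs_path: str | Path, markers_path: str | Path
) -> None:
    """Emit epochs.csv and markers.csv for a cohort."""
    epoch_frames = []
    marker_rows = []
    for rec in records:
        marker_rows.append(
            {
                "participant_id": rec.participant_id,
                "night_id": rec.night_id,
                "bedtime": rec.bedtime.isoformat(),
                "risetime": rec.risetime.isoformat(),
            }
        )
        for series in (rec.series_ref, rec.series_test):
            epoch_frames.append(
                pd.DataFrame(
                    {
                        "participant_id": rec.participant_id,
                        "night_id": rec.night_id,
                        "device_id": series.device_id,
                        "epoch_start": series.epoch_starts().map(pd.Timestamp.isoformat),
                        "epoch_len_s": series.epoch_len,
                        "state": series.states,
                    }
                )
            )
    pd.concat(epoch_frames, ignore_index=True).to_csv(epochs_path, index=False)
    pd.DataFrame(marker_rows, columns=MARKER_COLUMNS).to_csv(markers_path, index=False)


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: str | Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def read_cohort_csv(
    epochs_path: str | Path, markers_path: str | Path
) -> list[NightRecord]:
    """Read a cohort back from epochs.csv + markers.csv.

    Strictly validates states and timestamps, reporting offending CSV line
    numbers (header = line 1).  Marker rows without matching epochs yield
    records with empty series, which downstream QC flags as ``series_gap``.
    """
    epochs = pd.read_csv(epochs_path, dtype={"participant_id": str, "night_id": str,
                                             "device_id": str, "state": str})
    markers = pd.read_csv(markers_path, dtype={"participant_id": str, "night_id": str})
    _require_columns(epochs, EPOCH_COLUMNS, epochs_path)
    _require_columns(markers, MARKER_COLUMNS, markers_path)

    bad = ~epochs["state"].isin(sorted(VALID_STATES))
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise SchemaError(
            f"{epochs_path}: line {line}: invalid state "
            f"{epochs.loc[bad].iloc[0]['state']!r} (expected one of W, S)"
        )
    try:
        epochs["epoch_start"] = pd.to_datetime(epochs["epoch_start"])
    except (ValueError, TypeError) as err:
        raise SchemaError(f"{epochs_path}: unparseable epoch_start: {err}") from err
    for col in ("bedtime", "risetime"):
        try:
            markers[col] = pd.to_datetime(markers[col])
        except (ValueError, TypeError) as err:
            raise SchemaError(f"{markers_path}: unparseable {col}: {err}") from err

    grouped = {
        key: grp.sort_values("epoch_start")
        for key, grp in epochs.groupby(["participant_id", "night_id", "device_id"])
    }
    records = []
    for row in markers.itertuples(index=False):
        series = {}
        for device in ("ref", "test"):
            grp = grouped.get((row.participant_id, row.night_id, device))
            if grp is None:
                series[device] = EpochSeries(device, 60, row.bedtime, np.array([], dtype="<U1"))
                continue
            lens = grp["epoch_len_s"].unique()
            if len(lens) != 1:
                raise SchemaError(
                    f"{epochs_path}: mixed epoch lengths for "
                    f"{row.participant_id}/{row.night_id}/{device}"
                )
            series[device] = EpochSeries(
                device_id=device,
                epoch_len=int(lens[0]),
                start=grp["epoch_start"].iloc[0],
                states=grp["state"].to_numpy(),
            )
        records.append(
            NightRecord(
                participant_id=row.participant_id,
                night_id=row.night_id,
                bedtime=row.bedtime,
                risetime=row.risetime,
                series_ref=series["ref"],
                series_test=series["test"],
            )
        )
    return records


def _metrics_row(pid: str, nid: str, device: str, m) -> dict:
    return {
        "participant_id": pid,
        "night_id": nid,
        "device_id": device,
        "tib_h": round(m.tib, 4),
        "onset": m.sleep_onset.isoformat(),
        "offset": m.sleep_offset.isoformat(),
        "onset_latency_h": round(m.onset_latency, 4),
        "offset_latency_h": round(m.offset_latency, 4),
        "duration_h": round(m.duration, 4),
        "tst_h": round(m.tst, 4),
    }


def write_metrics_csv(paired: Sequence[PairedNight], path: str | Path) -> None:
    rows = []
    for p in paired:
        rows.append(_metrics_row(p.participant_id, p.night_id, "test", p.metrics_test))
        rows.append(_metrics_row(p.participant_id, p.night_id, "ref", p.metrics_ref))
    pd.DataFrame(rows).to_csv(path, index=False)


def write_qc_csv(flags: Iterable[QCFlag], path: str | Path) -> None:
    pd.DataFrame(
        [dataclasses.asdict(f) for f in flags],
        columns=["participant_id", "night_id", "code", "message"],
    ).to_csv(path, index=False)


def model_to_json(model: CalibrationModel, path: str | Path | None = None) -> dict:
    payload = {
        "dur_latency_coef": model.dur_latency_coef,
        "dur_intercept": model.dur_intercept,
        "tst_slope": model.tst_slope,
        "tst_intercept": model.tst_intercept,
        "provenance": model.provenance,
        "fit_diagnostics": model.fit_diagnostics,
    }
    if path is not None:
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")
    return payload


def model_from_json(source: str | Path | dict) -> CalibrationModel:
    payload = source if isinstance(source, dict) else json.loads(Path(source).read_text())
    return CalibrationModel(
        dur_latency_coef=float(payload["dur_latency_coef"]),
        dur_intercept=float(payload["dur_intercept"]),
        tst_slope=float(payload["tst_slope"]),
        tst_intercept=float(payload["tst_intercept"]),
        provenance=payload.get("provenance", "fitted"),
        fit_diagnostics=payload.get("fit_diagnostics"),
    )


def _jsonify(obj):
    if isinstance(obj, (ICCResult, DifferenceSummary)) or dataclasses.is_dataclass(obj):
        return {k: _jsonify(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_json(payload, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonify(payload), indent=2) + "\n")


def load_cohort_config(path: str | Path) -> CohortConfig:
    """Build a :class:`CohortConfig` from a YAML (or flat key: value) file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: expected a mapping of config keys")
    valid = {f.name for f in dataclasses.fields(CohortConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
    return CohortConfig(**raw)
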