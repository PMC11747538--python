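"""Per-night sleep summaries from an epoch-level sleep/wake series.

Seven scalar metrics describe a night: time in bed (TIB), sleep onset and
offset timestamps, onset and offset latencies, sleep duration and total
sleep time (TST).  Definitions follow standard actigraphy conventions:

* **sleep onset** — start of the first sleep-state epoch at/after bedtime;
* **sleep offset** — end boundary of the last sleep-state epoch before
  risetime (one epoch length after that epoch's start, i.e. one minute at
  60 s epochs);
* **onset latency** ``S`` — bedtime to sleep onset;
* **offset latency** — sleep offset to risetime;
* **duration** ``D`` — onset to offset, *including* intra-sleep wake;
* **TST** ``T`` — total sleep-epoch time between onset and offset.

All durations are carried in hours.  The partition identity
``TIB = S + D + offset latency`` holds exactly at epoch resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .records import NightRecord, EpochSeries, NightTruth, SLEEP

__all__ = [
    "SleepMetrics",
    "QCFlag",
    "MetricsError",
    "derive_sleep_metrics",
    "derive_cohort_metrics",
    "PairedNight",
    "truth_metrics",
    "paired_truth_metrics",
]

HOUR = pd.Timedelta(hours=1)


@dataclass(frozen=True)
class SleepMetrics:
    """The seven per-night scalar summaries for one device (hours)."""

    tib: float
    sleep_onset: pd.Timestamp
    sleep_offset: pd.Timestamp
    onset_latency: float
    offset_latency: float
    duration: float
    tst: float


@dataclass(frozen=True)
class QCFlag:
    """A per-night quality-control failure; flagged nights are excluded
    from agreement and calibration."""

    participant_id: str
    night_id: str
    code: str  # no_sleep_epoch | missing_marker | marker_order | series_gap
    message: str


class MetricsError(ValueError):
    """Raised when a night cannot yield valid sleep metrics."""

    def __init__(self, code: str, message: str):
        super().__init__(message)
        self.code = code


def derive_sleep_metrics(
    series: EpochSeries, bedtime: pd.Timestamp, risetime: pd.Timestamp
) -> SleepMetrics:
    """Derive the seven sleep summaries for one night and one device.

    Only epochs whose start lies in ``[bedtime, risetime)`` are considered,
    and they must tile that window exactly.

    Raises
    ------
    MetricsError
        ``marker_order`` if risetime <= bedtime; ``series_gap`` if the
        series does not cover the marker window; ``no_sleep_epoch`` if no
        epoch is scored as sleep.
    """
    bedtime = pd.Timestamp(bedtime)
    risetime = pd.Timestamp(risetime)
    if pd.isna(bedtime) or pd.isna(risetime):
        raise MetricsError("missing_marker", "bedtime or risetime missing")
    if risetime <= bedtime:
        raise MetricsError(
            "marker_order", f"risetime {risetime} not after bedtime {bedtime}"
        )

    starts = series.epoch_starts()
    in_window = (starts >= bedtime) & (starts < risetime)
    states = series.states[np.asarray(in_window)]
    starts = starts[in_window]
    n = states.size
    tib_td = risetime - bedtime
    step = pd.Timedelta(seconds=series.epoch_len)
    if n == 0 or starts[0] != bedtime or n * step != tib_td:
        raise MetricsError(
            "series_gap",
            f"series {series.device_id} does not tile [{bedtime}, {risetime}): "
            f"{n} epochs of {series.epoch_len} s",
        )

    sleep_idx = np.flatnonzero(states == SLEEP)
    if sleep_idx.size == 0:
        raise MetricsError("no_sleep_epoch", "night contains no sleep-state epoch")

    first, last = int(sleep_idx[0]), int(sleep_idx[-1])
    sleep_onset = starts[first]
    sleep_offset = starts[last] + step  # end boundary of the final sleep epoch

    epoch_h = series.epoch_len / 3600.0
    tib = n * epoch_h
    onset_latency = first * epoch_h
    duration = (last + 1 - first) * epoch_h
    offset_latency = tib - onset_latency - duration
    tst = int(sleep_idx.size) * epoch_h  # all sleep epochs lie in [onset, offset)

    return SleepMetrics(
        tib=tib,
        sleep_onset=sleep_onset,
        sleep_offset=sleep_offset,
        onset_latency=onset_latency,
        offset_latency=offset_latency,
        duration=duration,
        tst=tst,
    )


@dataclass(frozen=True)
class PairedNight:
    """Valid metrics for both devices on the same night."""

    participant_id: str
    night_id: str
    metrics_test: SleepMetrics
    metrics_ref: SleepMetrics


def derive_cohort_metrics(
    records: Iterable[NightRecord],
) -> tuple[list[PairedNight], list[QCFlag]]:
    """Derive metrics for every night; nights failing QC on either device
    are flagged and excluded from the paired output."""
    paired: list[PairedNight] = []
    flags: list[QCFlag] = []
    for rec in records:
        try:
            m_ref = derive_sleep_metrics(rec.series_ref, rec.bedtime, rec.risetime)
            m_test = derive_sleep_metrics(rec.series_test, rec.bedtime, rec.risetime)
        except MetricsError as err:
            flags.append(
                QCFlag(rec.participant_id, rec.night_id, err.code, str(err))
            )
            continue
        paired.append(
            PairedNight(rec.participant_id, rec.night_id, m_test, m_ref)
        )
    return paired, flags


def _metrics_from_truth(
    bedtime: pd.Timestamp, tib: float, latency: float, offset_latency: float, tst: float
) -> SleepMetrics:
    duration = tib - latency - offset_latency
    return SleepMetrics(
        tib=tib,
        sleep_onset=bedtime + latency * HOUR,
        sleep_offset=bedtime + (latency + duration) * HOUR,
        onset_latency=latency,
        offset_latency=offset_latency,
        duration=duration,
        tst=tst,
    )


def truth_metrics(rec: NightRecord, device: str) -> SleepMetrics:
    """Exact metrics from the generator's latent quantities (no epoch
    quantization); available only on synthetic records."""
    t: Optional[NightTruth] = rec.truth
    if t is None:
        raise ValueError("record carries no latent truth (not synthetic?)")
    if device == "test":
        return _metrics_from_truth(
            rec.bedtime, t.tib, t.onset_latency_test, t.offset_latency_test, t.tst_test
        )
    if device == "ref":
        return _metrics_from_truth(
            rec.bedtime, t.tib, t.onset_latency_ref, t.offset_latency_ref, t.tst_ref
        )
    raise ValueError(f"device must be 'test' or 'ref', got {device!r}")


def paired_truth_metrics(records: Iterable[NightRecord]) -> list[PairedNight]:
    """Paired latent-truth metrics for a synthetic cohort."""
    return [
        PairedNight(
            rec.participant_id,
            rec.night_id,
            truth_metrics(rec, "test"),
            truth_metrics(rec, "ref"),
        )
        for rec in records
    ]
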