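"""Core containers for epoch-scored dual-device actigraphy nights.

A night of wrist actigraphy is represented as two epoch-level sleep/wake
state series (one per device) bracketed by the user-marked bedtime and
risetime events.  Epoch timestamps denote the *start* of the epoch and
epochs are half-open intervals ``[start, start + epoch_len)``; a series
spans exactly ``[bedtime, risetime)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: Epoch state codes used throughout the package.
WAKE = "W"
SLEEP = "S"
VALID_STATES = frozenset({WAKE, SLEEP})


@dataclass
class EpochSeries:
    """One device's scored sleep/wake series for one night.

    Parameters
    ----------
    device_id
        Identifier of the scoring device (e.g. ``"test"`` or ``"ref"``).
    epoch_len
        Epoch length in seconds; must divide 60 evenly (30 s and 60 s are
        the epoch lengths in common actigraphy use).
    start
        Timestamp of the first epoch's start (the night's bedtime).
    states
        Ordered per-epoch states, each ``"W"`` or ``"S"``.
    """

    device_id: str
    epoch_len: int
    start: pd.Timestamp
    states: np.ndarray

    def __post_init__(self) -> None:
        if self.epoch_len <= 0 or 60 % self.epoch_len != 0:
            raise ValueError(
                f"epoch_len must be a positive divisor of 60 s, got {self.epoch_len}"
            )
        self.states = np.asarray(self.states, dtype="<U1")
        bad = set(np.unique(self.states)) - VALID_STATES
        if bad:
            raise ValueError(f"invalid epoch state codes: {sorted(bad)}")
        self.start = pd.Timestamp(self.start)

    @property
    def n_epochs(self) -> int:
        return int(self.states.size)

    @property
    def end(self) -> pd.Timestamp:
        """End boundary of the last epoch (exclusive)."""
        return self.start + pd.Timedelta(seconds=self.n_epochs * self.epoch_len)

    def epoch_starts(self) -> pd.DatetimeIndex:
        return self.start + pd.to_timedelta(
            np.arange(self.n_epochs) * self.epoch_len, unit="s"
        )


@dataclass(frozen=True)
class NightTruth:
    """Latent (pre-quantization) per-night quantities used by the generator.

    All durations in hours.  Epoch realization floors latent times onto the
    epoch grid, so metrics derived from the state series match these values
    only up to epoch quantization; tests of exact parameter recovery use
    the latent values directly.
    """

    tib: float
    onset_latency_test: float
    offset_latency_test: float
    duration_test: float
    tst_test: float
    onset_latency_ref: float
    offset_latency_ref: float
    duration_ref: float
    tst_ref: float


@dataclass
class NightRecord:
    """One night for one participant: event markers plus both device series."""

    participant_id: str
    night_id: str
    bedtime: pd.Timestamp
    risetime: pd.Timestamp
    series_ref: EpochSeries
    series_test: EpochSeries
    truth: Optional[NightTruth] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.bedtime = pd.Timestamp(self.bedtime)
        self.risetime = pd.Timestamp(self.risetime)
        if self.risetime <= self.bedtime:
            raise ValueError(
                f"risetime must follow bedtime for night "
                f"{self.participant_id}/{self.night_id}"
            )

    @property
    def tib_hours(self) -> float:
        return (self.risetime - self.bedtime) / pd.Timedelta(hours=1)
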