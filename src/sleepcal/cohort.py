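"""Synthetic dual-device actigraphy cohort generator.

Emulates a free-living validation study in which a small cohort wears two
actigraphs simultaneously: a 30 s epoch reference device and a 60 s epoch
test device.  The generator reproduces the error structure such studies
report for the test device — a large overestimate of sleep onset latency
(hence an underestimate of sleep duration), a near-zero offset-latency
bias, and a linear distortion of TST — so that the agreement, calibration
and sensitivity stages can be exercised end to end without external data.

Latent model per night (hours):

* ``TIB ~ Normal(tib_mean, tib_sd)`` truncated to ``[tib_min, tib_max]``
  and rounded to whole minutes (so both epoch grids tile it);
* test onset latency ``S = latency_shift + Gamma(shape, mean - shift)``;
* reference onset latency ``a*S + b + Normal(0, noise_sd_latency)``
  clipped to ``[0, TIB]``;
* offset latencies exponential with small means (test mean 0.03 h,
  reference mean near zero);
* reference intra-sleep wake (WASO): Poisson-count interruptions at
  ``waso_rate`` per hour of sleep, episode lengths geometric with mean
  ``waso_mean_len_min`` minutes; reference TST = duration - WASO;
* test TST is set by *inverting* the linear TST relation, so that
  ``ref TST = tst_slope * test TST + tst_intercept + Normal(0, noise_sd_tst)``
  holds and OLS on the cohort recovers the generating coefficients.

Latent times are floored onto each device's epoch grid when the state
sequences are realized; every :class:`~sleepcal.records.NightRecord`
carries its pre-quantization truth for parameter-recovery tests.
Infeasible draws (e.g. a TST target exceeding the test device's sleep
window) are redrawn up to a bounded retry count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .records import EpochSeries, NightRecord, NightTruth, SLEEP, WAKE

__all__ = ["CohortConfig", "generate_cohort", "GenerationError"]


class GenerationError(RuntimeError):
    """A night remained infeasible after the bounded retry budget."""


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters for the synthetic dual-device cohort.

    Defaults emulate the validation-study design this package targets:
    6 participants contributing 5-21 nights each, capped to 64 nights in
    total, with cross-device relations inverted from the published
    calibration (latency slope ``a = 1 - 0.59 = 0.41``, intercept
    ``b = -0.26`` h; TST slope 0.73, intercept 2.15 h) so that the
    uncalibrated duration bias is about -0.86 h and fitting recovers
    coefficients near the published ones.
    """

    n_participants: int = 6
    nights_low: int = 5
    nights_high: int = 21
    total_nights: Optional[int] = 64  # None = keep raw uniform draws
    epoch_len_ref: int = 30
    epoch_len_test: int = 60
    tib_mean: float = 6.9
    tib_sd: float = 0.7
    tib_low: float = 5.0
    tib_high: float = 10.0
    # test-device onset latency: shifted gamma, mean true_latency_mean
    true_latency_mean: float = 1.06
    latency_shift: float = 0.65
    latency_shape: float = 2.0
    # cross-device relations (reference = a*S + b, ref TST = m*T + t0)
    latency_slope_a: float = 0.41
    latency_intercept_b: float = -0.26
    tst_slope: float = 0.73
    tst_intercept: float = 2.15
    noise_sd_latency: float = 0.15
    noise_sd_tst: float = 0.40
    offset_latency_mean_test: float = 0.03
    offset_latency_mean_ref: float = 0.005
    waso_rate: float = 2.8  # interruptions per hour of sleep (reference)
    waso_mean_len_min: float = 2.5
    seed: int = 0
    max_retries: int = 200

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not 1 <= self.nights_low <= self.nights_high:
            raise ValueError("nights range must satisfy 1 <= low <= high")
        for ln in (self.epoch_len_ref, self.epoch_len_test):
            if ln <= 0 or 60 % ln != 0:
                raise ValueError(f"epoch length {ln}s must divide 60 s evenly")
        if self.tib_mean <= 0 or self.tib_low <= 0 or self.tib_high < self.tib_low:
            raise ValueError("invalid TIB parameters")
        for sd in (self.tib_sd, self.noise_sd_latency, self.noise_sd_tst):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if not 0 < self.latency_slope_a <= 1:
            raise ValueError("latency_slope_a must lie in (0, 1]")
        if not 0 < self.tst_slope <= 1:
            raise ValueError("tst_slope must lie in (0, 1]")
        if self.true_latency_mean < self.latency_shift:
            raise ValueError("true_latency_mean must be >= latency_shift")
        if self.waso_rate < 0 or self.waso_mean_len_min <= 0:
            raise ValueError("invalid WASO parameters")


def _nights_per_participant(cfg: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    counts = rng.integers(cfg.nights_low, cfg.nights_high + 1, cfg.n_participants)
    if cfg.total_nights is None:
        return counts
    target = cfg.total_nights
    if not cfg.n_participants * cfg.nights_low <= target <= cfg.n_participants * cfg.nights_high:
        raise ValueError("total_nights unreachable from the nights range")
    # cap/raise one participant at a time so the cohort totals exactly target
    while counts.sum() > target:
        counts[int(np.argmax(counts))] -= 1
    while counts.sum() < target:
        counts[int(np.argmin(counts))] += 1
    return counts


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, low: float, high: float
) -> float:
    if sd == 0:
        return float(np.clip(mean, low, high))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if low <= x <= high:
            return float(x)
    return float(np.clip(mean, low, high))


def _floor_epochs(hours: float, epoch_len: int) -> int:
    """Latent time -> whole epochs, flooring with a guard for exact grid points."""
    return int(math.floor(hours * 3600.0 / epoch_len + 1e-9))


def _draw_waso_hours(
    rng: np.random.Generator, sleep_hours: float, cfg: CohortConfig, epoch_len: int
) -> float:
    """Total intra-sleep wake: Poisson interruption count, geometric episode
    lengths (in epochs of the given device)."""
    if cfg.waso_rate == 0:
        return 0.0
    n_int = rng.poisson(cfg.waso_rate * sleep_hours)
    if n_int == 0:
        return 0.0
    mean_epochs = max(cfg.waso_mean_len_min * 60.0 / epoch_len, 1.0)
    lengths = rng.geometric(1.0 / mean_epochs, n_int)
    return float(lengths.sum()) * epoch_len / 3600.0


def _wake_episode_lengths(rng: np.random.Generator, total: int, mean_epochs: float) -> list[int]:
    """Split `total` wake epochs into geometric-length episodes."""
    out: list[int] = []
    left = total
    while left > 0:
        ln = min(int(rng.geometric(1.0 / max(mean_epochs, 1.0))), left)
        out.append(ln)
        left -= ln
    return out


def _realize_series(
    rng: np.random.Generator,
    device_id: str,
    epoch_len: int,
    start: pd.Timestamp,
    tib_minutes: int,
    latency_h: float,
    offset_latency_h: float,
    tst_h: float,
    waso_mean_len_min: float,
) -> Optional[EpochSeries]:
    """Realize latent per-night quantities as an epoch state sequence.

    Returns None when the quantized night is infeasible (caller retries).
    """
    n = tib_minutes * 60 // epoch_len
    n_lat = _floor_epochs(latency_h, epoch_len)
    n_off = _floor_epochs(offset_latency_h, epoch_len)
    n_dur = n - n_lat - n_off
    if n_dur < 2:
        return None
    n_tst = int(round(tst_h * 3600.0 / epoch_len))
    n_tst = min(max(n_tst, 2), n_dur)
    n_wake = n_dur - n_tst
    interior = n_dur - 2  # first and last sleep-window epochs stay asleep
    if n_wake > interior:
        return None

    states = np.full(n, WAKE, dtype="<U1")
    states[n_lat : n_lat + n_dur] = SLEEP
    if n_wake > 0:
        mean_epochs = waso_mean_len_min * 60.0 / epoch_len
        episodes = _wake_episode_lengths(rng, n_wake, mean_epochs)
        free = interior - n_wake
        gaps = rng.multinomial(free, np.full(len(episodes) + 1, 1.0 / (len(episodes) + 1)))
        pos = n_lat + 1
        for gap, ep in zip(gaps, episodes):
            pos += int(gap)
            states[pos : pos + ep] = WAKE
            pos += ep
    return EpochSeries(device_id=device_id, epoch_len=epoch_len, start=start, states=states)


def _draw_night(
    cfg: CohortConfig, rng: np.random.Generator, bedtime: pd.Timestamp
) -> Optional[tuple[EpochSeries, EpochSeries, NightTruth, int]]:
    """One attempt at a feasible night; returns None if any constraint fails."""
    tib_minutes = int(round(_truncated_normal(rng, cfg.tib_mean, cfg.tib_sd,
                                              cfg.tib_low, cfg.tib_high) * 60))
    tib = tib_minutes / 60.0

    gamma_mean = cfg.true_latency_mean - cfg.latency_shift
    s_test = cfg.latency_shift + (
        rng.gamma(cfg.latency_shape, gamma_mean / cfg.latency_shape)
        if gamma_mean > 0 else 0.0
    )
    off_test = rng.exponential(cfg.offset_latency_mean_test) if cfg.offset_latency_mean_test > 0 else 0.0
    off_ref = rng.exponential(cfg.offset_latency_mean_ref) if cfg.offset_latency_mean_ref > 0 else 0.0

    s_ref = cfg.latency_slope_a * s_test + cfg.latency_intercept_b
    if cfg.noise_sd_latency > 0:
        s_ref += rng.normal(0, cfg.noise_sd_latency)
    s_ref = float(np.clip(s_ref, 0.0, tib))

    d_test = tib - s_test - off_test
    d_ref = tib - s_ref - off_ref
    if d_test <= 0.5 or d_ref <= 0.5:
        return None

    waso_ref = _draw_waso_hours(rng, d_ref, cfg, cfg.epoch_len_ref)
    if waso_ref > 0.5 * d_ref:
        return None
    t_ref = d_ref - waso_ref

    eps = rng.normal(0, cfg.noise_sd_tst) if cfg.noise_sd_tst > 0 else 0.0
    t_test = (t_ref - cfg.tst_intercept - eps) / cfg.tst_slope
    if not 0.25 <= t_test <= d_test:
        return None

    series_ref = _realize_series(
        rng, "ref", cfg.epoch_len_ref, bedtime, tib_minutes,
        s_ref, off_ref, t_ref, cfg.waso_mean_len_min,
    )
    series_test = _realize_series(
        rng, "test", cfg.epoch_len_test, bedtime, tib_minutes,
        s_test, off_test, t_test, cfg.waso_mean_len_min,
    )
    if series_ref is None or series_test is None:
        return None
    truth = NightTruth(
        tib=tib,
        onset_latency_test=s_test,
        offset_latency_test=off_test,
        duration_test=d_test,
        tst_test=t_test,
        onset_latency_ref=s_ref,
        offset_latency_ref=off_ref,
        duration_ref=d_ref,
        tst_ref=t_ref,
    )
    return series_ref, series_test, truth, tib_minutes


def generate_cohort(config: CohortConfig) -> list[NightRecord]:
    """Generate the full cohort of dual-device night records.

    Reproducible: identical config (including seed) yields an identical
    cohort.  Raises :class:`GenerationError` if any night stays infeasible
    after ``config.max_retries`` redraws.
    """
    rng = np.random.default_rng(config.seed)
    counts = _nights_per_participant(config, rng)
    base = pd.Timestamp("2024-01-01 23:00:00")
    records: list[NightRecord] = []
    for p_idx, n_nights in enumerate(counts):
        pid = f"p{p_idx + 1:02d}"
        for night_idx in range(int(n_nights)):
            # bedtime jitter of +/-1 h around 23:00, on the minute grid
            jitter = int(rng.integers(-60, 61))
            bedtime = base + pd.Timedelta(days=p_idx * 30 + night_idx, minutes=jitter)
            drawn = None
            for _ in range(config.max_retries):
                drawn = _draw_night(config, rng, bedtime)
                if drawn is not None:
                    break
            if drawn is None:
                raise GenerationError(
                    f"night {pid}/n{night_idx + 1:02d} infeasible after "
                    f"{config.max_retries} retries; check the configuration "
                    "(e.g. latency or TST relations incompatible with TIB)"
                )
            series_ref, series_test, truth, tib_minutes = drawn
            records.append(
                NightRecord(
                    participant_id=pid,
                    night_id=f"n{night_idx + 1:02d}",
                    bedtime=bedtime,
                    risetime=bedtime + pd.Timedelta(minutes=tib_minutes),
                    series_ref=series_ref,
                    series_test=series_test,
                    truth=truth,
                )
            )
    return records
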