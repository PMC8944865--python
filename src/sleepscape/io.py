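"""Reading/writing actigraphy artifacts, nonwear detection, day segmentation.

Nonwear is detected on raw acceleration with the classical two-feature rule:
within a sliding window, an axis votes "off-wrist" when its SD falls below
13 mg or its value range below 50 mg; a window is nonwear when at least two
axes vote.  Analysis days run noon-to-noon so that a night's sleep is never
split, and a record enters the study only through its longest run of
consecutive low-nonwear days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .series import (
    MISSING,
    SECONDS_PER_DAY,
    STATE_SYMBOLS,
    SYMBOL_STATES,
    AccelRecord,
    SleepWakeSeries,
)


# ---------------------------------------------------------------------------
# CSV round-trips
# ---------------------------------------------------------------------------

def write_sleepwake(series: SleepWakeSeries, path) -> None:
    """CSV with columns timestamp (ISO-8601) and state in {S, W, M}."""
    df = pd.DataFrame(
        {
            "timestamp": series.epoch_times().strftime("%Y-%m-%dT%H:%M:%S"),
            "state": [STATE_SYMBOLS[s] for s in series.states],
        }
    )
    df.to_csv(path, index=False)


def read_sleepwake(path) -> SleepWakeSeries:
    """Read an epoch-level series; timestamp gaps are filled as missing."""
    df = pd.read_csv(path)
    for col in ("timestamp", "state"):
        if col not in df.columns:
            raise ValueError(f"missing required column '{col}'")
    ts = pd.to_datetime(df["timestamp"])
    if ts.duplicated().any():
        row = int(np.flatnonzero(ts.duplicated())[0])
        raise ValueError(f"duplicate timestamp at row {row}")
    if not ts.is_monotonic_increasing:
        row = int(np.flatnonzero(np.diff(ts.values).astype("timedelta64[ns]") < np.timedelta64(0))[0]) + 1
        raise ValueError(f"non-monotone timestamp at row {row}")
    bad = ~df["state"].isin(SYMBOL_STATES)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(f"unknown state symbol {df['state'].iloc[row]!r} at row {row}")
    if len(df) < 2:
        raise ValueError("series needs at least two epochs to infer the grid")
    diffs = ts.diff().dropna().dt.total_seconds().to_numpy()
    epoch_len = float(np.min(diffs))
    if epoch_len <= 0 or abs(epoch_len - round(epoch_len)) > 1e-9:
        raise ValueError("could not infer an integer epoch length")
    epoch_len = int(round(epoch_len))
    ratio = diffs / epoch_len
    if np.any(np.abs(ratio - np.round(ratio)) > 1e-9):
        row = int(np.flatnonzero(np.abs(ratio - np.round(ratio)) > 1e-9)[0]) + 1
        raise ValueError(f"irregular sampling at row {row}")
    n = int(round((ts.iloc[-1] - ts.iloc[0]).total_seconds() / epoch_len)) + 1
    states = np.full(n, MISSING, dtype=np.int8)
    idx = np.round((ts - ts.iloc[0]).dt.total_seconds().to_numpy() / epoch_len).astype(int)
    states[idx] = [SYMBOL_STATES[s] for s in df["state"]]
    return SleepWakeSeries(ts.iloc[0], epoch_len, states)


def write_accel(record: AccelRecord, path) -> None:
    df = pd.DataFrame(
        {
            "timestamp": record.sample_times().strftime("%Y-%m-%dT%H:%M:%S.%f"),
            "x": record.x,
            "y": record.y,
            "z": record.z,
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_accel(path, rtol: float = 1e-6) -> AccelRecord:
    df = pd.read_csv(path)
    for col in ("timestamp", "x", "y", "z"):
        if col not in df.columns:
            raise ValueError(f"missing required column '{col}'")
    ts = pd.to_datetime(df["timestamp"])
    if ts.duplicated().any():
        row = int(np.flatnonzero(ts.duplicated())[0])
        raise ValueError(f"duplicate timestamp at row {row}")
    if not ts.is_monotonic_increasing:
        raise ValueError("non-monotone timestamps")
    if len(df) < 2:
        raise ValueError("need at least two samples")
    diffs = ts.diff().dropna().dt.total_seconds().to_numpy()
    step = float(np.median(diffs))
    if np.any(np.abs(diffs - step) > max(rtol * step, 1e-9) + 1e-6):
        row = int(np.flatnonzero(np.abs(diffs - step) > max(rtol * step, 1e-9) + 1e-6)[0]) + 1
        raise ValueError(f"sample gap or irregular sampling at row {row}")
    return AccelRecord(ts.iloc[0], 1.0 / step, df["x"].to_numpy(), df["y"].to_numpy(), df["z"].to_numpy())


# ---------------------------------------------------------------------------
# Nonwear detection
# ---------------------------------------------------------------------------

@dataclass
class NonwearMask:
    """Per-epoch nonwear flags on a stated epoch grid."""

    start_time: pd.Timestamp
    epoch_len: int
    flags: np.ndarray  # bool

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        self.flags = np.asarray(self.flags, dtype=bool)

    @property
    def n_epochs(self) -> int:
        return self.flags.size

    def to_intervals(self) -> pd.DataFrame:
        """Half-open nonwear intervals as a BED-like table (start, end, label)."""
        from .series import run_length_encode

        vals, starts, lengths = run_length_encode(self.flags.astype(np.int8))
        rows = []
        for v, s, ln in zip(vals, starts, lengths):
            if v:
                t0 = self.start_time + pd.Timedelta(seconds=int(s) * self.epoch_len)
                t1 = t0 + pd.Timedelta(seconds=int(ln) * self.epoch_len)
                rows.append({"start": t0, "end": t1, "label": "nonwear"})
        return pd.DataFrame(rows, columns=["start", "end", "label"])


def detect_nonwear(
    record: AccelRecord,
    window: float = 60.0,
    step: float = 15.0,
    sd_thresh: float = 13.0,
    range_thresh: float = 50.0,
    axes_required: int = 2,
    epoch_len: int = 30,
) -> NonwearMask:
    """Two-feature sliding-window nonwear detector.

    Parameters are in minutes (window, step) and mg (thresholds).  A window is
    flagged when at least ``axes_required`` axes have SD < sd_thresh OR value
    range < range_thresh (strict <); flags propagate to every epoch the window
    covers, and the final mask is the union over stepped windows.
    """
    if window < step:
        raise ValueError("window must be >= step")
    if sd_thresh <= 0 or range_thresh <= 0:
        raise ValueError("thresholds must be positive")
    win_n = int(round(window * 60 * record.sampling_hz))
    step_n = int(round(step * 60 * record.sampling_hz))
    if record.n_samples < win_n:
        raise ValueError("record shorter than one window")
    sd_g, range_g = sd_thresh / 1000.0, range_thresh / 1000.0
    axes = record.axes()
    n_epochs = int(np.ceil(record.n_samples / (epoch_len * record.sampling_hz)))
    flags = np.zeros(n_epochs, dtype=bool)
    samples_per_epoch = epoch_len * record.sampling_hz
    for start in range(0, record.n_samples - win_n + 1, step_n):
        seg = axes[:, start : start + win_n]
        sds = seg.std(axis=1)
        ranges = seg.max(axis=1) - seg.min(axis=1)
        votes = int(np.sum((sds < sd_g) | (ranges < range_g)))
        if votes >= axes_required:
            e0 = int(np.floor(start / samples_per_epoch))
            e1 = int(np.ceil((start + win_n) / samples_per_epoch))
            flags[e0:e1] = True
    return NonwearMask(record.start_time, epoch_len, flags)


# ---------------------------------------------------------------------------
# Noon-to-noon segmentation and record inclusion
# ---------------------------------------------------------------------------

@dataclass
class NoonDay:
    """One noon-to-noon analysis day: [noon, next noon)."""

    day_index: int
    start: pd.Timestamp
    start_epoch: int
    n_epochs: int
    nonwear_hours: float
    valid: bool

    @property
    def end(self) -> pd.Timestamp:
        return self.start + pd.Timedelta(days=1)


def _next_noon(ts: pd.Timestamp) -> pd.Timestamp:
    noon = ts.normalize() + pd.Timedelta(hours=12)
    if noon < ts:
        noon += pd.Timedelta(days=1)
    return noon


def segment_noon_days(
    series: SleepWakeSeries,
    mask: NonwearMask | None = None,
    max_nonwear: float = 5.0,
) -> list[NoonDay]:
    """Partition a series into complete noon-to-noon days.

    Partial leading/trailing days are dropped.  ``nonwear_hours`` counts
    epochs flagged by the mask or marked missing; without a mask it is just
    the hours of missing state.  ``valid`` applies the strict
    ``nonwear_hours < max_nonwear`` rule.
    """
    epochs_per_day = SECONDS_PER_DAY // series.epoch_len
    first_noon = _next_noon(series.start_time)
    first_idx = series.index_at(first_noon)
    if first_noon != series.time_at(first_idx):
        raise ValueError("epoch grid not aligned to noon boundaries")
    days: list[NoonDay] = []
    nonwear = series.states == MISSING
    if mask is not None:
        if mask.epoch_len != series.epoch_len or mask.n_epochs < series.n_epochs:
            m = np.zeros(series.n_epochs, dtype=bool)
            k = min(mask.n_epochs, series.n_epochs)
            if mask.epoch_len != series.epoch_len:
                raise ValueError("mask epoch grid does not match series")
            m[:k] = mask.flags[:k]
            nonwear = nonwear | m
        else:
            nonwear = nonwear | mask.flags[: series.n_epochs]
    k = 0
    start = first_idx
    while start + epochs_per_day <= series.n_epochs:
        nw_hours = float(nonwear[start : start + epochs_per_day].sum() * series.epoch_len / 3600.0)
        days.append(
            NoonDay(
                day_index=k,
                start=series.time_at(start),
                start_epoch=start,
                n_epochs=epochs_per_day,
                nonwear_hours=nw_hours,
                valid=nw_hours < max_nonwear,
            )
        )
        k += 1
        start += epochs_per_day
    return days


def select_valid_span(
    days: list[NoonDay],
    max_nonwear: float = 5.0,
    min_consecutive_days: int = 4,
    max_days: int = 7,
) -> list[int]:
    """Longest run of consecutive valid days, capped at ``max_days``.

    Valid means ``nonwear_hours < max_nonwear`` (strict).  Ties go to the
    earliest run; an empty list is returned when the longest run is shorter
    than ``min_consecutive_days``.
    """
    best_start, best_len = 0, 0
    run_start, run_len = 0, 0
    for i, day in enumerate(days):
        if day.nonwear_hours < max_nonwear:
            if run_len == 0:
                run_start = i
            run_len += 1
            if run_len > best_len:
                best_start, best_len = run_start, run_len
        else:
            run_len = 0
    if best_len < min_consecutive_days:
        return []
    best_len = min(best_len, max_days)
    return [days[i].day_index for i in range(best_start, best_start + best_len)]
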