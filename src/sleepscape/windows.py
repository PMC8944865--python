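"""Sleep windows and the per-subject sleep index vector.

A sleep window is a stretch of dense sleep: maximal sleep runs are merged
whenever the pure-wake gap between them is 60 min or shorter.  Windows longer
than 3.75 h are "long" (the nightly sleep episode), the rest "short" (naps,
fragments).  Per noon-to-noon day the windows yield sleep time (ST), wake
time (WT), counts and lengths split by label, the day's sleep percentage, and
midawake bout counts split at 60 min; per subject, daily features are
summarized as mean (MN) and SD over valid days and combined with the
rhythm-related indexes into the fixed 21-component index vector that feeds
clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .series import MISSING, SLEEP, WAKE, SleepWakeSeries, run_length_encode
from .io import NoonDay

#: Fixed order of the 21 sleep indexes (3 general + MN/SD of 9 daily features).
INDEX_NAMES: list[str] = [
    "period",
    "amplitude",
    "total_windows",
    "phase_mn",
    "phase_sd",
    "st_long_mn",
    "st_long_sd",
    "wt_long_mn",
    "wt_long_sd",
    "st_short_mn",
    "st_short_sd",
    "wt_short_mn",
    "wt_short_sd",
    "sleep_percentage_mn",
    "sleep_percentage_sd",
    "len_long_mn",
    "len_long_sd",
    "len_short_mn",
    "len_short_sd",
    "n_long_mn",
    "n_long_sd",
]


@dataclass
class SleepWindow:
    """A merged interval of dense sleep.

    ``onset`` is the start of the first sleep epoch, ``offset`` the end of the
    last sleep epoch (half-open), so ``st + wt`` equals the window length.
    """

    onset: pd.Timestamp
    offset: pd.Timestamp
    st: float  # hours of sleep inside the window
    wt: float  # hours of wake inside the window
    label: str | None = None  # "long" | "short"

    @property
    def length_hours(self) -> float:
        return (self.offset - self.onset).total_seconds() / 3600.0


def build_windows(series: SleepWakeSeries, max_gap: float = 60.0) -> list[SleepWindow]:
    """Merge sleep runs into windows, ignoring wake gaps of ``max_gap`` min or
    less (inclusive).  Gaps containing missing epochs never merge, so windows
    hold no missing epochs and ST + WT equals the window length exactly."""
    vals, starts, lengths = run_length_encode(series.states)
    sleep_runs = [
        (int(s), int(s + ln)) for v, s, ln in zip(vals, starts, lengths) if v == SLEEP
    ]
    if not sleep_runs:
        return []
    max_gap_epochs = max_gap * 60.0 / series.epoch_len
    merged: list[list[tuple[int, int]]] = [[sleep_runs[0]]]
    for run in sleep_runs[1:]:
        prev_end = merged[-1][-1][1]
        gap = series.states[prev_end : run[0]]
        if run[0] - prev_end <= max_gap_epochs and not (gap == MISSING).any():
            merged[-1].append(run)
        else:
            merged.append([run])
    windows = []
    for group in merged:
        i0, i1 = group[0][0], group[-1][1]
        st = sum(b - a for a, b in group) * series.epoch_len / 3600.0
        wt = (i1 - i0) * series.epoch_len / 3600.0 - st
        windows.append(SleepWindow(series.time_at(i0), series.time_at(i1), st, wt))
    return windows


def label_windows(windows: list[SleepWindow], threshold: float = 3.75) -> list[SleepWindow]:
    """Label windows long (> threshold hours, strict) or short (otherwise)."""
    for w in windows:
        w.label = "long" if w.length_hours > threshold else "short"
    return windows


@dataclass
class DailyMetrics:
    """Window-derived quantities for one noon-to-noon day (hours / counts)."""

    day_index: int
    st_long: float = 0.0
    wt_long: float = 0.0
    st_short: float = 0.0
    wt_short: float = 0.0
    n_long: int = 0
    n_short: int = 0
    len_long: float = 0.0
    len_short: float = 0.0
    sleep_percentage: float = 0.0
    n_midawake_long: int = 0
    n_midawake_short: int = 0


def daily_metrics(day: NoonDay, windows: list[SleepWindow], series: SleepWakeSeries) -> DailyMetrics:
    """Compute a day's metrics from labelled windows.

    Windows belong to the day containing their onset (windows crossing noon
    are not split).  Sleep percentage counts *all* sleep epochs inside the day
    span, also those outside any window.  Midawake bouts are maximal wake runs
    between the day's first window onset and last window offset, long-term if
    >= 60 min, short-term if shorter.
    """
    m = DailyMetrics(day.day_index)
    todays = [w for w in windows if day.start <= w.onset < day.end]
    for w in todays:
        if w.label == "long":
            m.st_long += w.st
            m.wt_long += w.wt
            m.n_long += 1
            m.len_long += w.length_hours
        else:
            m.st_short += w.st
            m.wt_short += w.wt
            m.n_short += 1
            m.len_short += w.length_hours
    i0, i1 = day.start_epoch, day.start_epoch + day.n_epochs
    seg = series.states[i0:i1]
    m.sleep_percentage = 100.0 * float((seg == SLEEP).sum()) / day.n_epochs
    if todays:
        a = series.index_at(min(w.onset for w in todays))
        b = series.index_at(max(w.offset for w in todays) - pd.Timedelta(seconds=series.epoch_len)) + 1
        vals, starts, lengths = run_length_encode(series.states[a:b])
        for v, s, ln in zip(vals, starts, lengths):
            if v == WAKE:
                minutes = ln * series.epoch_len / 60.0
                if minutes >= 60.0:
                    m.n_midawake_long += 1
                else:
                    m.n_midawake_short += 1
    return m


@dataclass
class SleepIndexVector:
    """The 21 named per-subject sleep indexes, in the fixed registry order."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = [n for n in INDEX_NAMES if n not in self.values]
        if missing:
            raise ValueError(f"missing indexes: {missing}")
        self.values = {n: float(self.values[n]) for n in INDEX_NAMES}

    def to_series(self, name=None) -> pd.Series:
        return pd.Series(self.values, name=name)

    def __getitem__(self, key: str) -> float:
        return self.values[key]


def _mn_sd(values: list[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    mn = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return mn, sd


def compute_index_vector(daily: list[DailyMetrics], rhythm) -> SleepIndexVector:
    """Aggregate daily metrics and rhythm results into the 21-index vector.

    MN/SD use the sample SD (n-1 denominator; 0 for a single day).  General
    features: the whole-record period and amplitude from ``rhythm`` and the
    total window count across days.
    """
    if not daily:
        raise ValueError("no valid days")
    out: dict[str, float] = {
        "period": rhythm.period,
        "amplitude": rhythm.amplitude,
        "total_windows": float(sum(d.n_long + d.n_short for d in daily)),
        "phase_mn": rhythm.phase_mn,
        "phase_sd": rhythm.phase_sd,
    }
    for name in ("st_long", "wt_long", "st_short", "wt_short", "sleep_percentage", "len_long", "len_short", "n_long"):
        mn, sd = _mn_sd([getattr(d, name) for d in daily])
        out[f"{name}_mn"] = mn
        out[f"{name}_sd"] = sd
    return SleepIndexVector(out)


def windows_to_frame(windows: list[SleepWindow]) -> pd.DataFrame:
    """Interval-table export of labelled windows."""
    return pd.DataFrame(
        [
            {"onset": w.onset, "offset": w.offset, "label": w.label, "st": w.st, "wt": w.wt}
            for w in windows
        ],
        columns=["onset", "offset", "label", "st", "wt"],
    )
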