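"""Core epoch-level and sample-level containers.

The central intermediate of the whole pipeline is the epoch-level sleep/wake
series: a uniform grid of fixed-length scoring epochs (30 s by default), each
labelled sleep, wake, or missing.  Raw triaxial acceleration is carried as an
:class:`AccelRecord` until it is classified into such a series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Epoch state alphabet.  Missing covers both device nonwear and data gaps.
WAKE: int = 0
SLEEP: int = 1
MISSING: int = 2

STATE_SYMBOLS = {WAKE: "W", SLEEP: "S", MISSING: "M"}
SYMBOL_STATES = {"W": WAKE, "S": SLEEP, "M": MISSING}

SECONDS_PER_DAY = 86400


def states_from_string(text: str) -> np.ndarray:
    """Convert a compact 'SSWWM...' string to a state array (test helper)."""
    try:
        return np.array([SYMBOL_STATES[c] for c in text], dtype=np.int8)
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"unknown state symbol {exc}") from exc


@dataclass
class SleepWakeSeries:
    """Uniformly sampled per-epoch sleep/wake/missing sequence.

    Parameters
    ----------
    start_time
        Naive local timestamp of the first epoch's start.
    epoch_len
        Epoch length in seconds (must be positive).
    states
        int8 array over ``{WAKE, SLEEP, MISSING}``.
    """

    start_time: pd.Timestamp
    epoch_len: int
    states: np.ndarray

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        if self.epoch_len <= 0:
            raise ValueError("epoch_len must be positive")
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.ndim != 1:
            raise ValueError("states must be one-dimensional")
        bad = ~np.isin(self.states, (WAKE, SLEEP, MISSING))
        if bad.any():
            raise ValueError(f"invalid state value at index {int(np.argmax(bad))}")

    @property
    def n_epochs(self) -> int:
        return self.states.size

    @property
    def end_time(self) -> pd.Timestamp:
        return self.start_time + pd.Timedelta(seconds=self.epoch_len * self.n_epochs)

    @property
    def duration_hours(self) -> float:
        return self.n_epochs * self.epoch_len / 3600.0

    def epoch_times(self) -> pd.DatetimeIndex:
        return pd.date_range(
            self.start_time, periods=self.n_epochs, freq=pd.Timedelta(seconds=self.epoch_len)
        )

    def index_at(self, when: pd.Timestamp) -> int:
        """Epoch index containing ``when`` (may be out of range)."""
        offset = (pd.Timestamp(when) - self.start_time).total_seconds()
        return int(np.floor(offset / self.epoch_len))

    def time_at(self, index: int) -> pd.Timestamp:
        return self.start_time + pd.Timedelta(seconds=index * self.epoch_len)

    def slice_epochs(self, start: int, stop: int) -> "SleepWakeSeries":
        start = max(start, 0)
        stop = min(stop, self.n_epochs)
        return SleepWakeSeries(self.time_at(start), self.epoch_len, self.states[start:stop].copy())

    def runs(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Run-length encoding: (values, start indices, lengths)."""
        return run_length_encode(self.states)

    def copy(self) -> "SleepWakeSeries":
        return SleepWakeSeries(self.start_time, self.epoch_len, self.states.copy())

    def to_string(self) -> str:
        return "".join(STATE_SYMBOLS[s] for s in self.states)


def run_length_encode(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    values = np.asarray(values)
    if values.size == 0:
        return values[:0], np.empty(0, dtype=int), np.empty(0, dtype=int)
    change = np.flatnonzero(values[1:] != values[:-1]) + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [values.size])))
    return values[starts], starts, lengths


@dataclass
class AccelRecord:
    """Raw triaxial acceleration, uniformly sampled, in units of g."""

    start_time: pd.Timestamp
    sampling_hz: float
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        if self.sampling_hz <= 0:
            raise ValueError("sampling_hz must be positive")
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (self.x.shape == self.y.shape == self.z.shape) or self.x.ndim != 1:
            raise ValueError("x, y, z must be equal-length 1-d arrays")
        for name, arr in (("x", self.x), ("y", self.y), ("z", self.z)):
            if not np.isfinite(arr).all():
                raise ValueError(f"non-finite samples in axis {name}")

    @property
    def n_samples(self) -> int:
        return self.x.size

    @property
    def duration_seconds(self) -> float:
        return self.n_samples / self.sampling_hz

    def axes(self) -> np.ndarray:
        """Samples stacked as a (3, n) array in x, y, z order."""
        return np.vstack((self.x, self.y, self.z))

    def sample_times(self) -> pd.DatetimeIndex:
        step = pd.Timedelta(seconds=1.0 / self.sampling_hz)
        return pd.date_range(self.start_time, periods=self.n_samples, freq=step)
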