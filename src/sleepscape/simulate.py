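"""Synthetic actigraphy cohorts with known ground truth.

Sleep propensity is generated structurally: each night's onset and duration
are drawn explicitly from an archetype, then midawake bouts and daytime naps
are carved in.  This keeps the planted truth (onsets, period, per-day phase,
bout list) trivially recomputable from the emitted series, which is what makes
every downstream stage testable without real recordings.  A dynamical
two-process model is deliberately not used for generation; the van der Pol
oscillator is reserved for phase *fitting*.

Acceleration traces are synthesized from the state sequence: Gaussian noise
whose SD is state-dependent (low in sleep, high in wake), Poisson-arriving
1-10 s movement bursts during wake so that jerk spectra carry a wake
signature beyond variance alone, and near-constant signal during nonwear.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .series import (
    MISSING,
    SECONDS_PER_DAY,
    SLEEP,
    WAKE,
    AccelRecord,
    SleepWakeSeries,
    run_length_encode,
)

#: Default cohort start: a Monday noon, naive local time.
DEFAULT_START = pd.Timestamp("2024-01-01 12:00:00")

GRAVITY_BASELINE = (0.0, 0.0, 1.0)  # g, wrist roughly horizontal
NONWEAR_NOISE_SD = 0.001  # g; 1 mg, far below the 13 mg nonwear SD threshold


@dataclass
class ArchetypeSpec:
    """Parameters of one sleep phenotype used for subject generation.

    Clock hours are on a 0-24 h dial (``sleep_onset_mean=23.0`` is 11 pm);
    durations are hours, bout durations minutes.  ``circadian_period`` shifts
    each successive onset by ``period - 24`` h, emulating non-24-h sleep/wake
    cycles.  ``weekday_weekend_shift`` delays onsets on Friday and Saturday
    nights (social jet lag).
    """

    name: str
    sleep_onset_mean: float = 23.0
    onset_jitter_sd: float = 0.3
    sleep_duration_mean: float = 8.0
    sleep_duration_sd: float = 0.4
    midawake_rate: float = 1.0
    midawake_duration: tuple[float, float] = (15.0, 5.0)
    long_midawake_prob: float = 0.05
    nap_prob: float = 0.1
    nap_duration: tuple[float, float] = (30.0, 10.0)
    circadian_period: float = 24.0
    weekday_weekend_shift: float = 0.0

    def __post_init__(self) -> None:
        for p in (self.long_midawake_prob, self.nap_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.sleep_duration_mean <= 0 or self.midawake_duration[0] <= 0 or self.nap_duration[0] <= 0:
            raise ValueError("durations must be positive")
        if not 5.0 <= self.circadian_period <= 35.0:
            raise ValueError("circadian_period must be within [5, 35] h")
        if self.onset_jitter_sd < 0 or self.midawake_rate < 0:
            raise ValueError("rates and jitter must be non-negative")


#: Named archetypes mirroring distinctive phenotypes a cohort may contain.
ARCHETYPES: dict[str, ArchetypeSpec] = {
    "regular": ArchetypeSpec("regular"),
    "fragmented_insomnia": ArchetypeSpec(
        "fragmented_insomnia",
        sleep_onset_mean=23.5,
        onset_jitter_sd=0.6,
        sleep_duration_mean=5.5,
        sleep_duration_sd=0.8,
        midawake_rate=5.0,
        midawake_duration=(25.0, 10.0),
        long_midawake_prob=0.3,
        nap_prob=0.5,
        nap_duration=(45.0, 15.0),
    ),
    "shifted_phase": ArchetypeSpec(
        "shifted_phase",
        sleep_onset_mean=3.0,  # night person: sleeps 3 am - 11 am
        onset_jitter_sd=0.3,
    ),
    "long_period": ArchetypeSpec(
        "long_period",
        circadian_period=25.0,
        onset_jitter_sd=0.3,
    ),
}


@dataclass
class GroundTruth:
    """Everything planted into one generated subject."""

    archetype: str
    epoch_len: int
    n_days: int
    period: float  # h
    onsets_h: list[float] = field(default_factory=list)  # hours from series start
    durations_h: list[float] = field(default_factory=list)
    phases_h: list[float] = field(default_factory=list)  # per night, hours past that day's noon
    midawakes: list[tuple[float, float, bool]] = field(default_factory=list)
    # (start h, duration min, is_long)
    naps: list[tuple[float, float]] = field(default_factory=list)  # (start h, duration min)


def _quantize(hours: float, epoch_len: int) -> int:
    """Epoch index of an absolute offset in hours (round to nearest grid)."""
    return int(round(hours * 3600.0 / epoch_len))


def generate_subject(
    archetype: ArchetypeSpec,
    n_days: int,
    epoch_len: int = 30,
    seed: int = 0,
    start_time: pd.Timestamp = DEFAULT_START,
) -> tuple[SleepWakeSeries, GroundTruth]:
    """Generate one subject's multi-day sleep/wake series plus its truth.

    The series runs noon-to-noon over ``n_days`` days.  Each night k gets one
    intended sleep bout whose onset clock time drifts by k*(period-24) h,
    with archetype jitter, plus planted midawake bouts and optional naps.
    Deterministic for a fixed seed.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if SECONDS_PER_DAY % epoch_len != 0:
        raise ValueError("epoch_len must divide 24 h")
    rng = np.random.default_rng(seed)
    epochs_per_day = SECONDS_PER_DAY // epoch_len
    n_epochs = n_days * epochs_per_day
    states = np.full(n_epochs, WAKE, dtype=np.int8)
    truth = GroundTruth(archetype.name, epoch_len, n_days, archetype.circadian_period)

    for k in range(n_days):
        onset_clock = (
            archetype.sleep_onset_mean
            + k * (archetype.circadian_period - 24.0)
            + rng.normal(0.0, archetype.onset_jitter_sd)
        )
        if archetype.weekday_weekend_shift and k % 7 in (4, 5):  # Fri/Sat nights
            onset_clock += archetype.weekday_weekend_shift
        duration = float(np.clip(rng.normal(archetype.sleep_duration_mean, archetype.sleep_duration_sd), 2.0, 16.0))
        # hours past this day's noon; typical onset 23:00 -> 11 h past noon
        onset_h = k * 24.0 + (onset_clock - 12.0) % 24.0
        offset_h = onset_h + duration
        i0, i1 = _quantize(onset_h, epoch_len), _quantize(offset_h, epoch_len)
        i1 = min(i1, n_epochs)
        if i0 >= n_epochs:
            continue
        states[i0:i1] = SLEEP
        truth.onsets_h.append(i0 * epoch_len / 3600.0)
        truth.durations_h.append((i1 - i0) * epoch_len / 3600.0)
        truth.phases_h.append(((i0 + i1) / 2.0 * epoch_len / 3600.0) - k * 24.0)

        # midawake bouts carved out of the night, kept off the bout edges
        n_bouts = rng.poisson(archetype.midawake_rate)
        occupied: list[tuple[float, float]] = []
        for _ in range(n_bouts):
            is_long = rng.random() < archetype.long_midawake_prob
            if is_long:
                dur_min = float(max(60.0, rng.normal(90.0, 20.0)))
            else:
                mu, sd = archetype.midawake_duration
                dur_min = float(np.clip(rng.normal(mu, sd), 1.0, 59.0))
            dur_h = dur_min / 60.0
            lo, hi = onset_h + 0.25, offset_h - 0.25 - dur_h
            if hi <= lo:
                continue
            start = float(rng.uniform(lo, hi))
            if any(start < e + 0.1 and s - 0.1 < start + dur_h for s, e in occupied):
                continue  # skip overlapping draws; truth stays exact
            occupied.append((start, start + dur_h))
            j0, j1 = _quantize(start, epoch_len), _quantize(start + dur_h, epoch_len)
            states[j0:j1] = WAKE
            truth.midawakes.append(
                (j0 * epoch_len / 3600.0, (j1 - j0) * epoch_len / 60.0, is_long)
            )

        if rng.random() < archetype.nap_prob:
            mu, sd = archetype.nap_duration
            nap_min = float(np.clip(rng.normal(mu, sd), 5.0, 180.0))
            nap_start = k * 24.0 + float(rng.uniform(1.0, 5.0))  # 13:00-17:00
            j0, j1 = _quantize(nap_start, epoch_len), _quantize(nap_start + nap_min / 60.0, epoch_len)
            j1 = min(j1, n_epochs)
            if j1 <= n_epochs and not states[j0:j1].any():
                states[j0:j1] = SLEEP
                truth.naps.append((j0 * epoch_len / 3600.0, (j1 - j0) * epoch_len / 60.0))

    series = SleepWakeSeries(start_time, epoch_len, states)
    return series, truth


def _subject_seed(master_seed: int, archetype_name: str, index: int) -> int:
    """Per-subject seed derived from (master, archetype, within-archetype index).

    Depends on the archetype by name, not on its position in the spec list, so
    permuting the cohort spec leaves every subject's series unchanged.
    """
    tag = zlib.crc32(archetype_name.encode()) % 65536
    return (int(master_seed) + 1009 * tag + index) % (2**31)


def generate_cohort(
    specs: list[tuple[ArchetypeSpec, int]],
    n_days: int,
    seed: int = 0,
    epoch_len: int = 30,
    start_time: pd.Timestamp = DEFAULT_START,
) -> tuple[list[SleepWakeSeries], list[GroundTruth]]:
    """Generate a labelled cohort; per-subject seeds derive from the master seed."""
    if not specs:
        raise ValueError("empty cohort spec")
    for _, count in specs:
        if count < 1:
            raise ValueError("archetype counts must be >= 1")
    series_list: list[SleepWakeSeries] = []
    truths: list[GroundTruth] = []
    for archetype, count in specs:
        for i in range(count):
            sw, gt = generate_subject(
                archetype, n_days, epoch_len, _subject_seed(seed, archetype.name, i), start_time
            )
            series_list.append(sw)
            truths.append(gt)
    return series_list, truths


def synthesize_acceleration(
    series: SleepWakeSeries,
    sampling_hz: float = 20.0,
    noise_sd_sleep: float = 0.015,
    noise_sd_wake: float = 0.06,
    nonwear_spans: list[tuple[pd.Timestamp, pd.Timestamp]] | None = None,
    seed: int = 0,
    burst_rate_hz: float = 0.05,
    burst_sd: float = 0.25,
) -> AccelRecord:
    """Emulate a wrist accelerometer trace from a sleep/wake series.

    Each axis is a gravity baseline plus Gaussian noise whose SD depends on
    the epoch state, with sporadic high-amplitude movement bursts (Poisson
    arrivals, 1-10 s) during wake.  Samples inside ``nonwear_spans`` (and in
    missing epochs) collapse to baseline plus ~1 mg noise, i.e. below any
    sensible nonwear SD threshold.
    """
    if sampling_hz <= 0:
        raise ValueError("sampling_hz must be positive")
    if not noise_sd_wake > noise_sd_sleep >= 0:
        raise ValueError("require noise_sd_wake > noise_sd_sleep >= 0")
    spans = []
    for a, b in nonwear_spans or []:
        a, b = pd.Timestamp(a), pd.Timestamp(b)
        if b <= a:
            raise ValueError("empty nonwear span")
        spans.append((a, b))
    spans.sort()
    for (a0, b0), (a1, b1) in zip(spans, spans[1:]):
        if a1 < b0:
            raise ValueError("overlapping nonwear spans")

    rng = np.random.default_rng(seed)
    per_epoch = series.epoch_len * sampling_hz
    if abs(per_epoch - round(per_epoch)) > 1e-9:
        raise ValueError("sampling_hz must give an integer number of samples per epoch")
    per_epoch = int(round(per_epoch))
    n = series.n_epochs * per_epoch

    sd_by_state = np.array([noise_sd_wake, noise_sd_sleep, NONWEAR_NOISE_SD])
    sample_sd = np.repeat(sd_by_state[series.states], per_epoch)

    # nonwear spans override state-driven noise
    for a, b in spans:
        i0 = max(0, int(np.floor((a - series.start_time).total_seconds() * sampling_hz)))
        i1 = min(n, int(np.ceil((b - series.start_time).total_seconds() * sampling_hz)))
        sample_sd[i0:i1] = NONWEAR_NOISE_SD

    # Poisson movement bursts in wake samples (outside nonwear overrides)
    wake_samples = np.repeat(series.states == WAKE, per_epoch) & (sample_sd > NONWEAR_NOISE_SD)
    burst_extra = np.zeros(n)
    n_bursts = rng.poisson(burst_rate_hz * n / sampling_hz)
    if n_bursts:
        starts = rng.integers(0, n, size=n_bursts)
        lengths = (rng.uniform(1.0, 10.0, size=n_bursts) * sampling_hz).astype(int)
        for s, ln in zip(starts, lengths):
            burst_extra[s : s + ln] = burst_sd
    sample_sd = np.sqrt(sample_sd**2 + (burst_extra * wake_samples) ** 2)

    data = {}
    for axis, base in zip("xyz", GRAVITY_BASELINE):
        data[axis] = base + rng.normal(0.0, 1.0, size=n) * sample_sd
    return AccelRecord(series.start_time, sampling_hz, data["x"], data["y"], data["z"])


def generate_pseudo_flip_series(
    series: SleepWakeSeries,
    flip_rate: float,
    max_flip_run: int,
    seed: int = 0,
) -> tuple[SleepWakeSeries, GroundTruth | SleepWakeSeries]:
    """Insert short spurious wake/sleep runs into a clean series.

    Each epoch independently starts a flip run with probability ``flip_rate``;
    the run length is uniform on {1..max_flip_run} epochs and overlapping runs
    are unioned before inverting, so every affected non-missing epoch is
    inverted exactly once.  The clean input is the ground truth.
    """
    if not 0.0 <= flip_rate <= 1.0:
        raise ValueError("flip_rate must be in [0, 1]")
    if max_flip_run <= 0:
        raise ValueError("max_flip_run must be positive")
    rng = np.random.default_rng(seed)
    n = series.n_epochs
    starts = rng.random(n) < flip_rate
    mask = np.zeros(n, dtype=bool)
    if starts.any():
        lengths = rng.integers(1, max_flip_run + 1, size=n)
        for i in np.flatnonzero(starts):
            mask[i : i + lengths[i]] = True
    states = series.states.copy()
    flip = mask & (states != MISSING)
    states[flip] = np.where(states[flip] == SLEEP, WAKE, SLEEP)
    corrupted = SleepWakeSeries(series.start_time, series.epoch_len, states)
    return corrupted, series.copy()


def write_sleepwake_csv(series: SleepWakeSeries, path) -> None:
    """Write a series as CSV (ISO-8601 timestamp, state in {S, W, M})."""
    from .io import write_sleepwake

    write_sleepwake(series, path)
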