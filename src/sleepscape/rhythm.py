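"""Rhythm-related sleep indexes: period, amplitude, and circadian phase.

Period comes from the chi-square periodogram: the series of wake minutes per
10-min bin is folded at every candidate period P = K bins (5-35 h); the
statistic

    Qp(P) = N * sum_h n_h (M_h - Mbar)^2 / sum_i (x_i - Mbar)^2

(column means M_h over n_h samples, grand mean Mbar) is chi-square with K-1
degrees of freedom under the no-rhythm null, and the period is the candidate
maximizing Qp minus its 0.01-significance line.

Amplitude is the coefficient of variation (population SD / mean) of the
binned wake counts, a robust stand-in for circadian output strength when the
true oscillator amplitude is unobservable.

Phase uses the van der Pol limit cycle, the classical relaxation-oscillator
model of the human circadian pacemaker.  The normalized cycle (wake high,
minimum = subjective midnight) is slid over one noon-to-noon day of the 0/1
encoded series; the best-fitting shift places the minimum, and phase is the
duration from the preceding noon to that minimum, in (0, 24].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.stats import chi2

from .series import MISSING, SLEEP, WAKE, SleepWakeSeries
from .io import NoonDay


@dataclass
class BinnedActivity:
    """Wake minutes per fixed-length bin over the whole record."""

    start_time: pd.Timestamp
    bin_len: float  # minutes
    values: np.ndarray  # wake minutes per bin
    coverage: np.ndarray = field(default=None)  # fraction of non-missing epochs

    @property
    def n_bins(self) -> int:
        return self.values.size


def bin_wake(series: SleepWakeSeries, bin_len: float = 10.0) -> BinnedActivity:
    """Sum wake time (minutes) in consecutive bins; missing epochs add 0
    wake but are tracked in the coverage side-channel."""
    per_bin = bin_len * 60.0 / series.epoch_len
    if abs(per_bin - round(per_bin)) > 1e-9:
        raise ValueError("bin_len must be a multiple of the epoch length")
    per_bin = int(round(per_bin))
    n_bins = series.n_epochs // per_bin
    states = series.states[: n_bins * per_bin].reshape(n_bins, per_bin)
    wake_min = (states == WAKE).sum(axis=1) * series.epoch_len / 60.0
    coverage = (states != MISSING).mean(axis=1)
    return BinnedActivity(series.start_time, bin_len, wake_min.astype(float), coverage)


@dataclass
class PeriodogramResult:
    periods: np.ndarray  # hours
    qp: np.ndarray
    sig: np.ndarray  # 0.01-level chi-square threshold per period
    best_period: float  # hours


def chi_square_periodogram(
    binned: BinnedActivity,
    p_min: float = 5.0,
    p_max: float = 35.0,
    alpha: float = 0.01,
) -> PeriodogramResult:
    """Chi-square (Sokolove-Bushell) periodogram over integer bin multiples.

    The candidate grid is K = ceil(p_min/bin) .. floor(p_max/bin) bins; the
    selected period maximizes Qp - sig, ties going to the smallest period.
    """
    x = np.asarray(binned.values, dtype=float)
    n = x.size
    bin_h = binned.bin_len / 60.0
    if n * bin_h < 2 * p_max:
        raise ValueError("record must span at least twice the longest candidate period")
    mbar = x.mean()
    sst = float(((x - mbar) ** 2).sum())
    if sst == 0:
        raise ValueError("zero-variance series")
    k_lo = int(np.ceil(p_min / bin_h))
    k_hi = int(np.floor(p_max / bin_h))
    ks = np.arange(k_lo, k_hi + 1)
    qp = np.empty(ks.size)
    idx = np.arange(n)
    for j, k in enumerate(ks):
        cols = idx % k
        counts = np.bincount(cols, minlength=k)
        means = np.bincount(cols, weights=x, minlength=k) / counts
        ssb = float((counts * (means - mbar) ** 2).sum())
        qp[j] = n * ssb / sst
    sig = chi2.ppf(1.0 - alpha, ks - 1)
    best = int(np.argmax(qp - sig))
    periods = ks * bin_h
    return PeriodogramResult(periods, qp, sig, float(periods[best]))


def amplitude_cv(binned: BinnedActivity) -> float:
    """Coefficient of variation (population SD / mean) of binned wake."""
    x = np.asarray(binned.values, dtype=float)
    mean = x.mean()
    if mean <= 0:
        raise ValueError("mean of binned wake must be positive")
    return float(x.std(ddof=0) / mean)


# ---------------------------------------------------------------------------
# van der Pol phase fitting
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _vdp_cycle_cached(mu: float, n_points: int) -> tuple[float, ...]:
    """One normalized van der Pol cycle (min at index 0), unit period."""
    if mu <= 0:
        raise ValueError("mu must be positive")

    def rhs(t, yv):
        xx, vv = yv
        return [vv, mu * (1 - xx * xx) * vv - xx]

    # settle onto the limit cycle, then locate one full cycle between
    # successive upward zero crossings
    t_end = 80.0 + 20.0 * mu
    sol = solve_ivp(rhs, (0.0, t_end), [2.0, 0.0], rtol=1e-9, atol=1e-9, dense_output=True)
    ts = np.linspace(t_end * 0.6, t_end, 200000)
    xs = sol.sol(ts)[0]
    up = np.flatnonzero((xs[:-1] < 0) & (xs[1:] >= 0))
    if up.size < 3:
        raise RuntimeError("van der Pol integration did not converge to a cycle")
    # refine crossing times linearly
    def cross_t(i):
        t0, t1, x0, x1 = ts[i], ts[i + 1], xs[i], xs[i + 1]
        return t0 + (t1 - t0) * (-x0) / (x1 - x0)

    t_a, t_b = cross_t(up[-2]), cross_t(up[-1])
    cycle_len = t_b - t_a
    prev_len = cross_t(up[-2]) - cross_t(up[-3])
    if abs(cycle_len - prev_len) / cycle_len > 1e-4:
        raise RuntimeError("van der Pol cycle length not converged")
    tt = t_a + np.arange(n_points) / n_points * cycle_len
    w = sol.sol(tt)[0]
    w = (w - w.min()) / (w.max() - w.min())
    w = np.roll(w, -int(np.argmin(w)))
    return tuple(w)


def vdp_limit_cycle(mu: float = 1.0, period: float = 24.0, resolution: float = 1.0) -> np.ndarray:
    """Normalized van der Pol limit-cycle waveform over one period.

    Returns the cycle sampled every ``resolution`` minutes, min-max scaled to
    [0, 1] and rotated so the minimum (subjective midnight) sits at phase 0;
    the time axis is rescaled so one cycle spans ``period`` hours.
    """
    n_points = period * 60.0 / resolution
    if abs(n_points - round(n_points)) > 1e-9 or n_points < 4:
        raise ValueError("resolution must evenly divide the period")
    return np.asarray(_vdp_cycle_cached(float(mu), int(round(n_points))))


@dataclass
class PhaseFit:
    mu: float
    fitted_shift: float  # hours: waveform minimum relative to the day's first noon
    sse: float
    phase: float  # hours in (0, 24]


def fit_phase(
    day_series: SleepWakeSeries,
    waveform: np.ndarray,
    grid_min: float = 1.0,
    mu: float = 1.0,
) -> PhaseFit:
    """Fit the waveform to one noon-to-noon day by exhaustive shift search.

    Epochs are encoded wake=1, sleep=0 (missing as a neutral 0.5); the shift
    grid is ``grid_min``-minute steps over [0, 24) h, minimizing the SSE
    between the circularly shifted waveform and the encoded day.  Phase is the
    time from the day's starting noon to the fitted minimum, mapped to
    (0, 24]; SSE ties resolve to the smallest shift.
    """
    n = day_series.n_epochs
    if n * day_series.epoch_len != 86400:
        raise ValueError("fit_phase expects exactly one 24-h day")
    frac_missing = float((day_series.states == MISSING).mean())
    if frac_missing > 0.5:
        raise ValueError("day has less than 50% non-missing epochs")
    y = np.where(
        day_series.states == MISSING, 0.5, (day_series.states == WAKE).astype(float)
    )
    # resample the waveform onto the epoch grid (both cover exactly 24 h)
    src = np.arange(waveform.size) / waveform.size
    dst = np.arange(n) / n
    w = np.interp(dst, src, waveform, period=1.0)

    step_epochs = grid_min * 60.0 / day_series.epoch_len
    if abs(step_epochs - round(step_epochs)) > 1e-9 or step_epochs < 1:
        raise ValueError("grid_min must be a multiple of the epoch length")
    step_epochs = int(round(step_epochs))
    shifts = np.arange(0, n, step_epochs)
    # SSE(s) = ||y||^2 + ||w||^2 - 2 * corr(s); circular correlation via FFT
    corr = np.fft.irfft(np.fft.rfft(y) * np.conj(np.fft.rfft(w)), n)
    cand = corr[shifts]
    best = int(shifts[np.argmax(np.round(cand, 9))])  # ties -> smallest shift
    w_best = np.roll(w, best)
    sse = float(((y - w_best) ** 2).sum())
    tau = best * day_series.epoch_len / 3600.0
    phase = 24.0 if tau == 0.0 else tau
    return PhaseFit(mu=mu, fitted_shift=tau, sse=sse, phase=phase)


@dataclass
class RhythmResult:
    period: float  # hours
    amplitude: float
    phase_mn: float  # hours
    phase_sd: float
    phases: list[float] = field(default_factory=list)
    periodogram: PeriodogramResult | None = None


def rhythm_summary(
    series: SleepWakeSeries,
    days: list[NoonDay],
    bin_len: float = 10.0,
    p_min: float = 5.0,
    p_max: float = 35.0,
    alpha: float = 0.01,
    mu: float = 1.0,
    grid_min: float = 1.0,
) -> RhythmResult:
    """Whole-span period and amplitude plus per-day phase MN/SD.

    Phase statistics are naive (non-circular) over values in (0, 24], a
    documented convention; the phase waveform is the fixed 24-h cycle.
    """
    if not days:
        raise ValueError("no valid days")
    i0 = days[0].start_epoch
    i1 = days[-1].start_epoch + days[-1].n_epochs
    span = series.slice_epochs(i0, i1)
    binned = bin_wake(span, bin_len)
    pg = chi_square_periodogram(binned, p_min, p_max, alpha)
    amp = amplitude_cv(binned)
    waveform = vdp_limit_cycle(mu=mu, period=24.0, resolution=grid_min)
    phases = []
    for day in days:
        d = series.slice_epochs(day.start_epoch, day.start_epoch + day.n_epochs)
        phases.append(fit_phase(d, waveform, grid_min=grid_min, mu=mu).phase)
    arr = np.asarray(phases)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return RhythmResult(pg.best_period, amp, float(arr.mean()), sd, phases, pg)
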