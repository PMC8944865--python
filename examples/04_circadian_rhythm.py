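"""The three rhythm indexes: period, amplitude, and phase.

Period: chi-square periodogram of wake minutes per 10-min bin over 5-35 h,
maximizing Qp minus its 0.01-significance line.  Amplitude: coefficient of
variation (SD/mean) of the binned wake.  Phase: best-fit shift of the
normalized van der Pol limit cycle over one noon-to-noon day; the cycle
minimum marks subjective midnight.
"""

import numpy as np

import sleepscape as ss
from sleepscape.rhythm import (BinnedActivity, amplitude_cv, bin_wake,
                               chi_square_periodogram, fit_phase, vdp_limit_cycle)

NOON = ss.generate_subject(ss.ARCHETYPES["regular"], 1, seed=0)[0].start_time

# reference square waves: 24-h period, duty 1/3
for lo, hi, closed_form in ((0, 10, np.sqrt(2)), (3, 7, 4 * np.sqrt(2) / 13)):
    x = np.where((np.arange(864) % 144) < 48, float(hi), float(lo))
    b = BinnedActivity(NOON, 10.0, x)
    print(f"square wave {lo}-{hi} min: CV = {amplitude_cv(b):.5f} "
          f"(closed form {closed_form:.5f})")

# a 25-h subject: the periodogram finds the planted period
arch = ss.ArchetypeSpec("drifting", circadian_period=25.0, onset_jitter_sd=0.1)
series, _ = ss.generate_subject(arch, 6, seed=4)
binned = bin_wake(series)
pg = chi_square_periodogram(binned)
print(f"\n25-h archetype: estimated period {pg.best_period:.2f} h, "
      f"amplitude {amplitude_cv(binned):.2f}")

# phase of one noon-to-noon day
waveform = vdp_limit_cycle(mu=1.0, period=24.0, resolution=1.0)
day = series.slice_epochs(0, 2880)
fit = fit_phase(day, waveform)
print(f"day-1 phase: {fit.phase:.2f} h after the preceding noon "
      f"(subjective midnight ~{(12 + fit.phase) % 24:.1f}:00 clock time)")
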