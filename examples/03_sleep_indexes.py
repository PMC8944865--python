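"""Compute the 21 sleep indexes for one subject.

The smoothed series is segmented into noon-to-noon days, sleep windows are
built by merging sleep runs across wake gaps of up to 60 min and labelled
long (> 3.75 h) or short, and daily quantities are summarized as mean (MN)
and day-to-day SD, joined by the whole-record rhythm indexes.
"""

import sleepscape as ss

series, truth = ss.generate_subject(ss.ARCHETYPES["fragmented_insomnia"], n_days=6, seed=3)
config = ss.PipelineConfig()
vec = ss.extract_indexes(series, config)

print("21 sleep indexes (fragmented-insomnia archetype, 6 days):")
for name, value in vec.values.items():
    print(f"  {name:22s} {value:8.3f}")
print()
print(f"-> ST long MN {vec['st_long_mn']:.2f} h of sleep inside the nightly window,")
print(f"   WT long MN {vec['wt_long_mn']:.2f} h awake inside it (midawake),")
print(f"   period {vec['period']:.2f} h and phase MN {vec['phase_mn']:.2f} h "
      "(subjective midnight relative to the preceding noon).")
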