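"""Enumerate the acquisition protocol and account for failed measurements.

The canonical design images 15 subjects under 10 settings (5 ART
frame-averaging levels in focus; 5 focus offsets at ART 100; one
bottom-positioned acquisition), 3 repetitions of 7 sections each.  Each
five-setting arm therefore holds 1575 theoretical measurements.
"""

import numpy as np

from octhaze import enumerate_protocol, art_arm, focus_arm, generate_study
from octhaze.stats import failure_summary

slots = enumerate_protocol(n_subjects=15, repetitions=3, sections=7)
print(f"total slots            : {len(slots)}")
print(f"ART arm (in focus)     : {len(art_arm(slots))}")
print(f"focus arm (ART 100)    : {len(focus_arm(slots))}")

# simulate the study, then mark some out-of-focus acquisitions as failed
table = generate_study(slots, seed=7)
rng = np.random.default_rng(7)
bad = rng.choice(table.index[table["focus"] != 0], 500, replace=False)
table.loc[bad, "vri"] = np.nan
table.loc[bad, "failed"] = True

print(failure_summary(slots, table))
# failure_pct is the percentage of theoretical measurements in each arm
# for which no valid VRI exists (never acquired or measurement failed).
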