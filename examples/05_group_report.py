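"""Group-level reporting: mean +/- SD, percent change, one-way ANOVA.

Simulates three treatment cohorts that differ in antibody decay length
(deeper penetration for the co-administration groups), measures the
accumulation density of each section, and aggregates the per-section
metric the way the study reports its figures.
"""

import pandas as pd

from histoflux import (SyntheticSpec, accumulation, generate_section,
                       summarize, tumor_volume)

cohorts = {"TZB": 15.0, "TZB+ATV": 25.0, "TZB+CTX": 30.0}
rows = []
for g_idx, (group, lam) in enumerate(cohorts.items()):
    for k in range(5):  # five sections per group
        section, _ = generate_section(
            SyntheticSpec(rng_seed=100 + 100 * g_idx + k,
                          decay_length_um=lam, noise_sd=50.0))
        rows.append({"group": group, "metric": "accumulation_AU_per_um2",
                     "value": accumulation(section).accumulation_density})

report = summarize(pd.DataFrame(rows), reference_group="TZB")
print(report.to_string(index=False))
print()
print(f"tumor volume at enrollment-size caliper reading (7.07 x 10 mm): "
      f"{tumor_volume(7.07, 10.0):.0f} mm^3")
# pct_change_vs_ref mirrors the study's percent-increase reporting; the
# omnibus ANOVA F/p tests whether the groups differ at all.
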