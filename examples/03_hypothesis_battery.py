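"""Simulate the full study design and run the directional Welch battery.

Generates 99 microcap KP values over the 11 tested conditions (3 batches x
1 coupon x 3 technical replicates each) around the study's measured
equilibrium levels, averages technical replicates, and runs the six
one-tailed Welch comparisons for size exclusion, volume exclusion and
attachment at alpha = 0.05.
"""
import pandas as pd

from microcap import stats
from microcap.plan import KPNoise, simulate_study

dataset = simulate_study(noise=KPNoise(batch_cv=0.05, microcap_cv=0.05), seed=42)
print(f"dataset: {len(dataset)} microcaps, "
      f"{dataset.groupby(['microsphere_type', 'nanodextran']).ngroups} conditions")

battery = stats.run_hypothesis_battery(dataset)
with pd.option_context("display.width", 120):
    print(battery[["effect", "comparison", "t", "df", "p_one_tailed", "significant"]]
          .to_string(index=False))
# With the study's own 30% size effect baked into the true levels, the
# size-exclusion comparison rejects decisively. Volume exclusion does not:
# the sphere-free and sphere-loaded levels differ by ~3%, below the batch
# noise. The amino-sphere / CM-tracer pairing sits ~20% above its controls
# in the measured levels, so at 5% batch CV the simulation flags it - the
# physical assay saw the same trend without reaching significance; the
# opposite pairing (DEAE tracer / carboxyl spheres) shows no effect.
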