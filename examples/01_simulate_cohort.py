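"""Simulate a preterm-to-term control cohort and inspect its composition.

The generator draws gestational age at birth from a preterm/term mixture,
scans subjects between 31 and 46 weeks postmenstrual age, and grows each of
the 21 brain segments along a logistic curve with a small male-female offset
and noise proportional to the mean.
"""

import numpy as np

from neonorm import synthetic as syn
from neonorm import volumes as vol

spec = syn.CohortSpec(n=500, seed=1)
demo, segs = syn.generate_controls(spec)
agg = vol.compute_aggregates(segs)

print(f"n = {len(demo)} controls")
print(f"female fraction      : {(demo['sex'] == 'female').mean():.3f}"
      f"  (spec {spec.sex_ratio_female})")
print(f"preterm fraction     : {(demo['ga_birth'] < 37).mean():.3f}"
      f"  (spec {spec.preterm_fraction})")
print(f"PMA at scan (weeks)  : median {demo['pma_scan'].median():.2f}, "
      f"range {demo['pma_scan'].min():.2f}-{demo['pma_scan'].max():.2f}")
print(f"TTV at term (cm^3)   : "
      f"{agg.loc[demo['pma_scan'] > 39, 'ttv'].median():.0f} (median)")
print(f"cerebellum share of TTV: "
      f"{(segs['cerebellum'] / agg['ttv']).median():.3f}")

# The three whole-brain denominators nest: TTV <= TBV <= ICV for everyone.
assert bool(np.all(agg["ttv"] <= agg["tbv"]) and np.all(agg["tbv"] <= agg["icv"]))
print("whole-brain nesting TTV <= TBV <= ICV holds for all subjects")
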