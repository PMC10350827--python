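"""Whole-brain covariation analysis: segment z-scores against WBV z-scores.

Regressing a segment's deviation on the matched whole-brain deviation
(tissue vs TTV, ventricles vs TBV, eCSF vs ICV) separates brain-size-
mediated deviation from segment-specific deviation: the median-regression
intercept at WBV z = 0 is the WBV-adjusted group median z-score.
"""

import pandas as pd

from neonorm import pipeline as pl
from neonorm import synthetic as syn

cfg = pl.AnalysisConfig(seed=4, n_restarts=2, n_boot=500,
                        measures_absolute=("ttv", "cerebellum", "brainstem"),
                        measures_relative=())

demo_c, segs_c = syn.generate_controls(syn.CohortSpec(n=300, seed=40))
models = pl.fit_models(demo_c, segs_c, cfg)

# cerebellum: genuine segment-specific deficit; brainstem: untouched, so any
# deviation it shows is mediated by overall brain size
dev = syn.DeviationSpec(mean_shift={"cerebellum": -1.5})
demo_a, segs_a, _ = syn.generate_atypical(
    syn.CohortSpec(n=25, seed=41, group="atypical"), dev,
    {"cerebellum": models[("absolute", "cerebellum")]})

scores = pl.score_cohort(models, pd.concat([demo_c, demo_a]),
                         pd.concat([segs_c, segs_a]), cfg)
table = pl.run_covariation_analysis(scores, cfg)

cols = ["measure", "wbv_measure", "adjusted_median_atypical",
        "adjusted_median_control", "p_boot"]
print(table[cols].to_string(index=False, float_format="%.3f"))
print("\nthe cerebellar deficit survives WBV adjustment (segment-specific);"
      "\nthe brainstem's adjusted median stays near 0 (size-mediated only)")
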