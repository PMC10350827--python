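"""Groupwise comparison of deviation z-scores: atypical vs control.

Per measure, the two groups' z-scores are compared by Mann-Whitney U with
Cliff's delta as effect size, FDR-adjusted within the absolute and relative
tables separately.
"""

import pandas as pd

from neonorm import pipeline as pl
from neonorm import synthetic as syn

cfg = pl.AnalysisConfig(
    seed=2, n_restarts=2,
    measures_absolute=("ttv", "total_cortical_gm", "total_wm", "cerebellum"),
    measures_relative=("cerebellum",))

demo_c, segs_c = syn.generate_controls(syn.CohortSpec(n=300, seed=20))
models = pl.fit_models(demo_c, segs_c, cfg)

dev = syn.DeviationSpec(mean_shift={"cerebellum": -1.8})
demo_a, segs_a, _ = syn.generate_atypical(
    syn.CohortSpec(n=25, seed=21, group="atypical"), dev,
    {"cerebellum": models[("absolute", "cerebellum")]})

demo = pd.concat([demo_c, demo_a])
segs = pd.concat([segs_c, segs_a])
scores = pl.score_cohort(models, demo, segs, cfg)
table = pl.run_group_comparison(scores, cfg)

cols = ["kind", "measure", "median_z_atypical", "cliffs_delta",
        "effect_category", "p_fdr", "stars"]
print(table[cols].to_string(index=False, float_format="%.3g"))
print("\nthe injected cerebellar deficit is significant with a large effect;"
      "\nundisturbed measures stay near z = 0 and non-significant")
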