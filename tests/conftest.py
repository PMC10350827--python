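import numpy as np
import pandas as pd
import pytest

from neonorm import normative as nm
from neonorm import synthetic as syn


@pytest.fixture(scope="session")
def control_cohort():
    """Training controls: n=160, mixed preterm/term, seeded."""
    return syn.generate_controls(syn.CohortSpec(n=160, seed=11))


@pytest.fixture(scope="session")
def heldout_cohort():
    """Independent same-spec controls for calibration checks."""
    return syn.generate_controls(syn.CohortSpec(n=150, seed=12))


@pytest.fixture(scope="session")
def cerebellum_model(control_cohort):
    demo, segs = control_cohort
    return nm.fit_normative(demo, segs["cerebellum"], "cerebellum",
                            seed=7, n_restarts=2)


@pytest.fixture(scope="session")
def segment_models(control_cohort, cerebellum_model):
    """Absolute-volume models for a few segments, keyed by measure."""
    demo, segs = control_cohort
    models = {"cerebellum": cerebellum_model}
    for measure in ("occipital_wm", "thalamus"):
        models[measure] = nm.fit_normative(demo, segs[measure], measure,
                                           seed=7, n_restarts=2)
    return models
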