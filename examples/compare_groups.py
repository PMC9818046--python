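"""Robust covariate-adjusted between-group comparison of cohort outcomes.

Generates a synthetic two-arm cohort (22 controls, 20 ET) from the
structural-equation generator, then compares each outcome between
groups with robust regression adjusting for grip strength and tactile
acuity, mirroring a standard outcomes table.
"""

import pandas as pd

from tremorlab.cohort import compare_outcomes
from tremorlab.synth import CohortGenSpec, generate_cohort

table, _ = generate_cohort(CohortGenSpec(seed=11))
results = compare_outcomes(
    table,
    ["width_threshold", "postural_rms_weighted", "ftm_ab", "abilhand",
     "bbt", "nhpt"],
)

with pd.option_context("display.width", 120):
    print(results.round(3).to_string(index=False))

# 'robust_difference' is the adjusted ET-minus-control mean difference
# in the outcome's natural units; a 95% CI that crosses zero reads as
# "no-difference".  In this pure-direct-effect cohort the proprioceptive
# threshold shows no group difference while tremor amplitude and the
# functional scores do.
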