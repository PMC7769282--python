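"""Generate the default synthetic cohort and its nested case-control sample.

The generator reproduces the study design exactly: a cohort of 2,364
first-time pregnancies with 23 preterm-PE and 74 term-PE cases, and a
nested case-control set of all 97 cases plus 335 random controls carrying
inverse-sampling-fraction weights.
"""

import numpy as np

from pe_triage import synthcohort as sc

design = sc.CohortDesign()
specs = sc.default_biomarker_specs()
cohort = sc.generate_cohort(design, specs, seed=1)
cc = sc.sample_case_control(cohort, design.n_controls_selected, seed=2)

print("cohort size:", len(cohort))
print("outcome counts:", cohort["outcome"].value_counts().to_dict())
print("case-control rows:", len(cc))
print("control weight:", round(float(cc.loc[cc.outcome == 'none', 'weight'].iloc[0]), 4))
w = cc["weight"].to_numpy()
case = (cc["outcome"] != "none").to_numpy()
print("weighted PE prevalence:", round(w[case].sum() / w.sum(), 5), "(cohort: 97/2364 =", round(97 / 2364, 5), ")")

# The counts are fixed by design, so they match the study tables exactly;
# the weighted prevalence shows the sampling weights put case-control
# quantities back on the cohort scale.
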