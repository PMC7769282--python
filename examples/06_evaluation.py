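"""Use-case evaluation of the named model suite.

Every model x use case gets constraint-respecting cut-offs, weighted
metrics with bootstrap CIs, and paired superiority tests against the
reference models; infeasible pairs (expected for the any-PE rule-in at
PPV >= 0.15) are reported as such. A per-10,000-screened projection turns
the preterm rule-in row into expected clinic-scale counts.
"""

from pe_triage import models, qc, synthcohort as sc
from pe_triage.evaluate import project_per_10000, run_use_cases

_, cc, _, _ = sc.default_dataset(seed=1, with_technical=False)
matrix = qc.prepare_model_matrix(cc, ["PlGF", "DLG", "1-HGP", "MAP", "BMI"])
w = matrix["weight"].to_numpy()

report = run_use_cases(models.table3_models(), matrix, matrix["outcome"], w, B=300, seed=4)

cols = ["model", "feasible", "ppv", "npv", "sensitivity", "specificity"]
for uc in ("rule_in_preterm_pe", "rule_out_any_pe", "rule_in_any_pe"):
    print(f"\n== {uc} ==")
    print(report.loc[report.use_case == uc, cols].round(3).to_string(index=False))

row = report[(report.use_case == "rule_in_preterm_pe") & (report.model == "PlGF||DLG")].iloc[0]
if row["feasible"]:
    proj = project_per_10000(row["sensitivity"], row["specificity"], 23 / 2364)
    print("\nper-10,000 projection for rule-in PlGF||DLG:")
    print(proj.round(1))
# Rows with feasible=False mean no cut-off combination met that use case's
# predictive-value floor - a first-class result, not an error.
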