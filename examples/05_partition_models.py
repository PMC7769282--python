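"""PlGF-first recursive partitioning under predictive-value constraints.

The rule-in model (preterm PE) maximizes sensitivity subject to a weighted
PPV >= 0.05; the rule-out model (any PE) maximizes specificity subject to a
weighted NPV >= 0.99. PlGF is imposed as the first partition step.
"""

from pe_triage import models, qc, synthcohort as sc

_, cc, _, _ = sc.default_dataset(seed=1, with_technical=False)
matrix = qc.prepare_model_matrix(cc, ["PlGF", "DLG", "1-HGP", "MAP", "BMI"])
w = matrix["weight"].to_numpy()
preterm = (matrix["outcome"] == "preterm_pe").to_numpy()
any_pe = (matrix["outcome"] != "none").to_numpy()

rule_in = models.build_partition_model(
    matrix, preterm, "rule-in", [["PlGF"], ["DLG"]],
    weights=w, pv_target=0.05, subgroup_labels=any_pe,
)
print("rule-in PlGF||DLG:")
for s in rule_in.steps:
    print(f"  flag {'+'.join(s.predictors)} {'<=' if s.direction == 'down' else '>='} "
          f"{'(skipped)' if s.cutoff is None else round(s.cutoff, 4)}")
print("  training metrics:", {k: round(v, 3) for k, v in rule_in.training_metrics.items()})

rule_out = models.build_partition_model(
    matrix, any_pe, "rule-out", [["PlGF"], ["DLG"], ["1-HGP"]],
    weights=w, pv_target=0.99, subgroup_labels=any_pe,
)
print("\nrule-out PlGF||DLG||1-HGP:")
for s in rule_out.steps:
    print(f"  flag {'+'.join(s.predictors)} {'<=' if s.direction == 'down' else '>='} "
          f"{'(skipped)' if s.cutoff is None else round(s.cutoff, 4)}")
print("  training metrics:", {k: round(v, 3) for k, v in rule_out.training_metrics.items()})
# Cut-offs are on the log scale of the analysis matrix. The rule-in PPV is a
# cohort-scale post-test risk (>= 5%); the rule-out NPV >= 0.99 means the
# un-flagged group's residual PE risk is at most 1%.
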