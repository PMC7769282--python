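"""Univariable pre-selection with permutation FDR.

Each candidate predictor is scored by AUROC (Mann-Whitney statistic, DeLong
CI) and a median effect size per outcome; a variable is selected when
AUROC > 0.60 with a lower CI bound >= 0.50. The panel-level FDR of that rule
is estimated by outcome-label permutation with pi0 = 1.
"""

from pe_triage import select, synthcohort as sc

_, cc, _, _ = sc.default_dataset(seed=1, with_technical=False)

variables = ["MAP", "BMI", "PlGF", "DLG", "1-HGP", "choline", "isoleucine"]
report = select.build_predictor_report(cc, variables, B_boot=300, B_perm=300, seed=3)

t = report.table
cols = ["variable", "auroc", "ci_low", "ci_high", "effect", "direction", "selected"]
print(t.loc[t.outcome == "preterm_pe", cols].round(3).to_string(index=False))
print("\npanel FDR by outcome:", {k: round(v, 3) for k, v in report.fdr.items()})
print("modelling set (selected for any PE):", report.modelling_set)
# The preterm column is small (23 cases), so its selections carry a high
# permutation FDR; the any-PE selection is what feeds the modelling stage.
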