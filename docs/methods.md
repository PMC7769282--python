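# Methods

`pe-triage` re-implements, as a tested library, a biomarker-triage analysis
for early-pregnancy preeclampsia (PE) risk prediction: synthetic cohort
generation, assay quality control, univariable predictor pre-selection with
permutation FDR, PLS-DA and PlGF-first recursive-partitioning classifiers,
and case-control-weighted evaluation against pre-defined clinical use
cases. This note records the models, the defaults and why, the numerical
choices, and the limits of what the synthetic data can show.

## Synthetic cohort generator

The generator stands in for a prospective pregnancy cohort with a nested
case-control metabolomics study. It is calibrated to the printed design:
2,364 subjects, 23 preterm-PE and 74 term-PE cases (97 PE in total), and a
nested case-control set of all cases plus 335 uniformly sampled controls.
Counts are **fixed by design**, not binomial draws, so design-level
quantities are exactly testable. Note the printed cohort description
(2,364 total; 2,266 non-PE) is internally inconsistent by one subject; we
keep the total and the case count, giving 2,267 non-PE subjects and a
control weight of 2267/335 ≈ 6.767. This makes the weighted PE prevalence
of the case-control set equal 97/2364 to machine precision.

### Effect calibration

Each biomarker is generated from an equal-variance two-Gaussian model on
its natural model scale (log scale for analytes, identity for MAP and
BMI). For that family,

    AUROC = Φ( Δμ / (σ√2) )

so given a target median fold change FC (Δμ = ln FC) or median difference
(Δμ = Δ) *and* a target AUROC, the shared scale

    σ = |Δμ| / (√2 · Φ⁻¹(AUROC))

reproduces both targets simultaneously. A neutral effect with an
informative AUROC target (or vice versa) is rejected as infeasible. The
choice of this generative family is ours; the source tables print only the
per-outcome medians/fold changes and AUROCs, not a distributional form.

Per-outcome targets (preterm PE, term PE, any PE) for the ten headline
variables (MAP, BMI, PlGF, DLG, 1-HGP, choline, isoleucine,
2-hydroxybutanoate, NG-monomethyl-L-arginine, decanoylcarnitine) come from
the published effect-size table. A variable with no predictive performance
for an outcome draws that outcome's cases from the control distribution.
The remaining metabolites of the 43-analyte panel are represented by 36
null log-normal analytes so panel-level quantities (permutation FDR,
association screens) run at realistic width.

One control distribution per analyte has to serve all outcomes, but the
per-outcome calibrations imply slightly different σ. The control scale is
taken from the preterm calibration when present, then term, then any-PE;
each case subtype keeps its own calibrated (Δμ, σ). Consequence: the
per-outcome targets are reproduced exactly by the dedicated two-group
sampler (`draw_calibrated`), while AUROCs measured across outcomes inside
one mixed cohort are emergent and only approximately equal to the printed
values. Inter-analyte correlation is zero by default; the source reports
no correlation structure, so joint-model performance on synthetic data is
indicative only.

Control locations are configuration, not data: metabolite relative
concentrations centre at ~1, MAP at 79.2 mmHg, BMI at 23.9 kg/m², and PlGF
at a control median of 0.040 ng/mL — chosen so the clinically relevant low
tail (printed cut-offs of 0.00526 and 0.00702 ng/mL) lies well inside the
support, about 1.8–2.1 control SDs below the median.

### Technical structure

The assay campaign is simulated at the level the downstream statistics
see: samples are assigned to batches (default 6) by stratified
randomisation over centre × ethnicity × PE status (shuffled round-robin
within stratum); assayed analytes get per-batch multiplicative effects
exp(N(0, batch_sd)) with batch_sd = 0.05 by default, multiplicative
technical noise exp(N(0, cv)) with cv = 0.08 per measurement event, 9
pooled-QC replicates per batch, technical duplicates for 15% of samples
(count rounded half up — 65 pairs for 432 samples), and missing cells at a
per-analyte rate (default 5%, below the 20% filter). Chromatography,
calibration curves and drift are out of scope. MAP, BMI and PlGF are
treated as non-assayed (clinical or externally measured) and bypass the
batch machinery.

## Quality control

Batch scaling divides each value by (batch median / overall median), so
every batch's post-scaling median equals the overall pre-scaling median;
the operation is idempotent. Medians include pooled-QC samples by default
(config-exposed; the source does not say which convention it used).
Imprecision is summarized as %CV = 100·sd/mean over all pooled-QC
replicates, and as the root-mean-square of per-pair CVs over technical
duplicates (mean-of-pairs available by option; the aggregation is not
specified in the source). Missingness is computed over study samples only.
The selection rule is: missingness < 20% (named exceptions allowed) and
both CVs ≤ 25%, with a named one-metric exception list mirroring the two
exceptions the original analysis allowed. Duplicates are collapsed to
their per-subject mean after scaling and before modelling. Analytes are
natural-log transformed for modelling ("log" unqualified in the source);
MAP and BMI enter untransformed; modelling is complete-case.

## Predictor pre-selection

AUROC is the Mann–Whitney rank statistic with ties counted one half,
folded to ≥ 0.5 with the natural direction recorded. The 95% CI is
DeLong's (the source does not name a method; a bootstrap CI would be the
natural sensitivity check). Selection requires AUROC > 0.60 (strict) and a
lower CI bound ≥ 0.50 (inclusive), independently per outcome; the
modelling set is the any-PE selection. Effects are medians on the original
pre-log scale (difference for MAP/BMI, fold change for analytes) with
stratified percentile bootstrap CIs.

The panel FDR of the selection rule is estimated by outcome-label
permutation: FDR = π₀ · E[null discoveries] / observed discoveries, capped
at 1, with the conservative π₀ = 1. Labels are permuted jointly across all
variables per replicate, preserving inter-variable correlation. The
production replicate count is 2×10⁴; tests and the default pipeline run
scaled-down counts (hundreds), which changes only Monte-Carlo error. An
exact-enumeration mode over all label arrangements exists for tiny inputs
and anchors the estimator's oracle test.

## Models

**PLS-DA.** Predictors are standardized on training data, the class
encoded ±1, and components extracted by standard PLS regression
(scikit-learn's implementation behind this module's surface — PLS is prior
art here, not a contribution of this package). The continuous score is
oriented so cases score higher. Default components: min(2, #predictors).
With one predictor the score is an affine transform of it, so its AUROC is
preserved exactly — a tested invariant.

**Recursive partitioning.** A model is 1–3 ordered steps, PlGF alone
imposed first; each step flags the risky tail of a score (single predictor
with a fixed risk direction — PlGF↓, DLG↑, 1-HGP↓, MAP↑, BMI↑ — or a
two-predictor PLS-DA score) and flagged subjects exit with the positive
call; the terminal default is negative. Two-predictor step scorers are
trained on the high-PlGF subgroup, delimited by the PlGF value that
maximizes unweighted accuracy for any-PE prediction (ties toward the
larger retained subgroup), biasing those sub-models toward non-placental
disease.

Cut-off selection maximizes weighted sensitivity subject to weighted PPV ≥
target (rule-in) or weighted specificity subject to weighted NPV ≥ target
(rule-out), evaluated on the **final** model. Because a step's score does
not depend on earlier cut-offs, the final positive set is the union of the
per-step tails, so cut-offs interact only through that union. The default
search is therefore a joint scan over a candidate grid — every observed
value for 1–2 step models, ~55 quantile candidates per step (always
keeping the eight most extreme values per tail) for 3-step models — which
is exact on the grid and exact outright on small inputs. A greedy
per-step alternative (`search="greedy"`) is provided; it is order-sensitive
for rule-out objectives, where the NPV floor is typically attainable only
once all steps are placed, which is why the joint search is the default.
Ties prefer a higher constraint metric, then fewer flagged. Whether the
original cut-offs were tuned jointly or per partition is not stated; both
are available. When no cut-off combination satisfies the floor the result
is an infeasible-model object, not an error — the expected outcome for the
any-PE rule-in use case at PPV ≥ 0.15.

## Evaluation

All predictive values use inverse-sampling-fraction weights (cases 1,
controls 2267/335), making PPV and NPV interpretable as post-test risks on
the cohort scale; this weighting is an assumption of this package — the
source does not state how its case-control metrics map to the cohort
scale, and its printed PPVs are not exactly reproducible by any simple
prevalence arithmetic we tried. The central correctness property — the
weighted case-control PPV estimates the full-cohort PPV at the same
cut-offs — is verified by simulation.

Use cases: rule-in preterm PE at PPV ≥ 0.05; rule-in any PE at PPV ≥ 0.15;
rule-out any PE at NPV ≥ 0.99. For the preterm objective, term-PE subjects
remain in the evaluation set as non-events (config-exposed).

Bootstrap CIs are percentile 2.5/97.5 over class-stratified resamples of
subjects with cut-offs held fixed; degenerate replicates are dropped with
a reported count. Superiority of one model over another is tested on
paired per-replicate metric differences; the test statistic is the mean
difference divided by the replicate standard deviation (the bootstrap
spread *is* the standard error of the paired difference — dividing it by
√B would test the in-sample difference against zero and reject about half
the time for exchangeable models), one-tailed against Student t with B−1
degrees of freedom, Bonferroni-corrected over the reference comparisons.
Per-10,000-screened projections are the expected confusion counts at a
supplied cohort prevalence; they conserve the total and are linear in
prevalence.

## Degenerate inputs and tie-breaks

- All-tied AUROC input: 0.5 with a degenerate-CI flag.
- Zero observed discoveries: FDR undefined (NaN), never 0.
- Empty flagged/unflagged set: PPV/NPV NaN; such candidates are infeasible
  whenever a positive floor is demanded.
- Constant predictors are dropped from PLS-DA with a warning; a fully
  constant step would flag nobody.
- High-PlGF subgroups too small or single-class fall back to the full
  sample for the step's PLS-DA fit.
- Confusion cells are accumulated per side (flagged and unflagged sums),
  never by subtraction, so empty sets are exact zeros.

## Determinism and problem sizes

Every stochastic operation takes an explicit seed; compound stages spawn
child seeds from a single `SeedSequence`, and identical config + seed
yields byte-identical artifacts. Calibration-recovery checks use 20,000
subjects per group, where the Monte-Carlo error of an AUROC is ≈ 0.003, so
a ±0.01 check is meaningful. The pipeline's default replicate counts
(B = 500) and the test suite's smaller ones trade Monte-Carlo precision
for speed; production-scale counts are configuration.

## Limitations

Synthetic data carry the *marginal* structure of the study — prevalences,
per-outcome effect sizes, batch/duplicate/missingness artefacts — but not
its joint structure: inter-analyte correlations, non-Gaussian tails,
centre effects on analytes, or gestational-age trends (the source reports
none) are absent. Passing calibration and constraint tests therefore
validates the pipeline's machinery, not the clinical performance of any
marker combination; multivariable results on synthetic data should not be
read as estimates of real-data performance. The headline real-data numbers
(sensitivities at the use-case floors, the printed cut-offs) depend on the
undeposited study data and are documented here as context only.
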