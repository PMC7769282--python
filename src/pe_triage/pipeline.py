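"""End-to-end pipeline runner.

Stages run in order: synthetic cohort (or external CSV) -> QC -> predictor
selection -> model suite -> use-case evaluation. Every stage's decisions are
appended to a structured JSON-lines log; identical config and seed yield
byte-identical artifacts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import models, qc, select, synthcohort
from .config import PipelineConfig
from .errors import PipelineError
from .evaluate import run_use_cases


class _Log:
    def __init__(self, path: Path):
        self.path = path
        self.entries: list[dict] = []

    def add(self, stage: str, **info) -> None:
        self.entries.append({"stage": stage, **info})

    def write(self) -> None:
        with open(self.path, "w") as fh:
            for e in self.entries:
                fh.write(json.dumps(e, sort_keys=True, default=str) + "\n")


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run all stages and write artifacts under ``config.output_dir``.

    Returns a name -> path map of the written artifacts. A stage failure
    raises with the stage name; artifacts already written are preserved.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _Log(out / "pipeline_log.jsonl")
    artifacts: dict[str, Path] = {"log": log.path}
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = ss.generate_state(8) % (2**31)
    specs = synthcohort.default_biomarker_specs(config.n_null_metabolites)

    try:
        stage = "synthcohort"
        if config.input_csv is None:
            design = config.design
            cohort = synthcohort.generate_cohort(design, specs, int(stage_seeds[0]))
            cc = synthcohort.sample_case_control(cohort, config.n_controls, int(stage_seeds[1]))
            assay = synthcohort.inject_technical_structure(
                cc, specs, n_batches=config.n_batches,
                dup_fraction=config.dup_fraction, seed=int(stage_seeds[2]),
            )
            artifacts["cohort"] = out / "cohort.csv"
            cohort.to_csv(artifacts["cohort"], index=False)
            artifacts["assay"] = out / "assay_measurements.csv"
            assay.measurements.to_csv(artifacts["assay"], index=False)
            log.add(stage, n_cohort=len(cohort), n_case_control=len(cc),
                    n_measurements=len(assay.measurements),
                    n_duplicate_pairs=len(assay.duplicate_pairs))
        else:
            cc = pd.read_csv(config.input_csv)
            assay = None
            log.add(stage, skipped=True, input_csv=config.input_csv)

        stage = "qc"
        if assay is not None:
            assayed = [s.name for s in specs if s.assayed and s.name in assay.measurements]
            scaled = qc.scale_batches(assay, assayed)
            report = qc.compute_qc_metrics(scaled)
            report = qc.select_assays(
                report, config.qc_cv_threshold, config.qc_missing_threshold,
                config.missingness_exceptions, config.one_metric_exceptions,
            )
            artifacts["qc_report"] = out / "qc_report.csv"
            report.to_csv(artifacts["qc_report"])
            screen = qc.screen_associations(
                scaled.study.assign(pe=scaled.study["outcome"] != "none"),
                {"batch": "categorical", "pe": "categorical", "centre": "categorical"},
            )
            artifacts["association_screen"] = out / "association_screen.csv"
            screen.to_csv(artifacts["association_screen"], index=False)
            collapsed = qc.collapse_duplicates(scaled)
            analyte_vars = report.selected
            log.add(stage, n_selected_assays=len(analyte_vars),
                    n_flagged_associations=int(screen["flagged"].sum()))
        else:
            collapsed = cc
            analyte_vars = [
                s.name for s in specs if s.assayed and s.name in collapsed.columns
            ]
            log.add(stage, skipped=True)

        stage = "select"
        variables = ["MAP", "BMI", "PlGF"] + analyte_vars
        variables = [v for v in variables if v in collapsed.columns]
        report = select.build_predictor_report(
            collapsed, variables, B_boot=config.B_boot, B_perm=config.B_perm,
            seed=int(stage_seeds[3]),
        )
        artifacts["predictor_report"] = out / "predictor_report.csv"
        report.to_csv(artifacts["predictor_report"])
        (out / "fdr.json").write_text(json.dumps(report.fdr, indent=2, sort_keys=True))
        artifacts["fdr"] = out / "fdr.json"
        log.add(stage, modelling_set=report.modelling_set, fdr=report.fdr)

        stage = "models+evaluate"
        headline = [m for m in models.table3_models()
                    if all(p in collapsed.columns for p in m.predictors)]
        matrix = qc.prepare_model_matrix(
            collapsed, sorted({p for m in headline for p in m.predictors})
        )
        weights = matrix["weight"].to_numpy() if "weight" in matrix else None
        evaluation = run_use_cases(
            headline, matrix, matrix["outcome"], weights,
            targets=config.targets, B=config.B_eval, seed=int(stage_seeds[4]),
        )
        artifacts["evaluation"] = out / "evaluation.csv"
        evaluation.to_csv(artifacts["evaluation"], index=False)
        log.add(stage, n_models=len(headline), n_dropped=matrix.attrs.get("n_dropped", 0),
                n_rows=len(evaluation))
    except Exception as exc:
        log.add(stage, error=str(exc))
        log.write()
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    log.write()
    return artifacts
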