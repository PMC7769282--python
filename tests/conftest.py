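import numpy as np
import pandas as pd
import pytest

from pe_triage import qc, synthcohort as sc


@pytest.fixture(scope="session")
def default_specs():
    return sc.default_biomarker_specs()


@pytest.fixture(scope="session")
def default_cohort(default_specs):
    return sc.generate_cohort(sc.CohortDesign(), default_specs, seed=11)


@pytest.fixture(scope="session")
def default_cc(default_cohort):
    return sc.sample_case_control(default_cohort, 335, seed=12)


@pytest.fixture(scope="session")
def default_assay(default_cc, default_specs):
    return sc.inject_technical_structure(default_cc, default_specs, seed=13)


@pytest.fixture(scope="session")
def model_matrix(default_cc):
    """Analysis-ready log-scale matrix of the headline predictors."""
    return qc.prepare_model_matrix(
        default_cc.copy(), ["PlGF", "DLG", "1-HGP", "MAP", "BMI"]
    )


def small_assay(values_by_batch: dict[int, list[float]], name: str = "A") -> sc.AssayDataset:
    """Hand-built single-analyte AssayDataset for QC unit tests."""
    rows = []
    i = 0
    for batch, vals in values_by_batch.items():
        for v in vals:
            rows.append(
                {
                    "sample_id": f"s{i}_m1",
                    "subject_id": f"s{i}",
                    "role": "study",
                    "batch": batch,
                    "outcome": "none",
                    "centre": "c",
                    "ethnicity": "e",
                    name: v,
                }
            )
            i += 1
    for batch in values_by_batch:
        for r in range(2):
            rows.append(
                {
                    "sample_id": f"qc_b{batch}_r{r}",
                    "subject_id": "QCpool",
                    "role": "qc_pool",
                    "batch": batch,
                    "outcome": "none",
                    "centre": "pool",
                    "ethnicity": "pool",
                    name: np.nan,
                }
            )
    return sc.AssayDataset(pd.DataFrame(rows), [name], [])
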