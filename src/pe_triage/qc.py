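"""Data pre-processing and quality assurance.

Batch median scaling, imprecision metrics from pooled-QC replicates and
technical duplicates, missingness accounting, the assay selection rule
(%CV <= 25 for both metrics, missingness < 20% with named exceptions),
randomisation bias screens, and construction of the analysis-ready
(log-transformed, complete-case) model matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError
from .synthcohort import AssayDataset

CV_THRESHOLD = 25.0
MISSING_THRESHOLD = 0.20


# ---------------------------------------------------------------------------
# batch scaling
# ---------------------------------------------------------------------------


def scale_batches(
    dataset: AssayDataset,
    analytes: list[str] | None = None,
    include_qc_in_medians: bool = True,
) -> AssayDataset:
    """Scale listed analytes per batch to remove multiplicative batch effects.

    Each value is divided by (batch median / overall median) of its analyte,
    so every batch's post-scaling median equals the overall pre-scaling
    median. The operation is idempotent. A batch in which an analyte is
    entirely missing is left unscaled for that batch and recorded in
    ``dataset.measurements.attrs["unscaled"]``.
    """
    out = dataset.copy()
    df = out.measurements
    analytes = list(dataset.analytes) if analytes is None else list(analytes)
    unknown = set(analytes) - set(dataset.analytes)
    if unknown:
        raise ConfigurationError(f"unknown analytes: {sorted(unknown)}")
    if include_qc_in_medians:
        median_mask = np.ones(len(df), dtype=bool)
    else:
        median_mask = (df["role"] != "qc_pool").to_numpy()
    flagged: list[tuple[str, int]] = []
    for name in analytes:
        vals = df[name].to_numpy(dtype=float)
        overall = np.nanmedian(vals[median_mask]) if np.isfinite(vals[median_mask]).any() else np.nan
        for b, rows in df.groupby("batch").indices.items():
            rows = np.asarray(rows)
            sub = rows[median_mask[rows]]
            bvals = vals[sub]
            if not np.isfinite(bvals).any():
                flagged.append((name, int(b)))
                continue
            bmed = np.nanmedian(bvals)
            vals[rows] = vals[rows] * (overall / bmed)
        df[name] = vals
    df.attrs["unscaled"] = flagged
    return out


# ---------------------------------------------------------------------------
# QC metrics and assay selection
# ---------------------------------------------------------------------------


@dataclass
class QCReport:
    """Per-analyte QC summary and selection decisions."""

    table: pd.DataFrame  # index: analyte; cols: missing_fraction, cv_pool, cv_duplicates, selected, exception_reason
    cv_threshold: float = CV_THRESHOLD
    missing_threshold: float = MISSING_THRESHOLD

    @property
    def selected(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path)

    def to_json(self, path: str) -> None:
        self.table.reset_index(names="analyte").to_json(path, orient="records", indent=2)


def _pair_cv(a: float, b: float) -> float:
    m = (a + b) / 2.0
    sd = abs(a - b) / np.sqrt(2.0)  # sample sd of a pair
    return 100.0 * sd / m


def compute_qc_metrics(dataset: AssayDataset, duplicate_cv: str = "rms") -> QCReport:
    """Imprecision and missingness metrics per analyte.

    ``cv_pool`` is 100*sd/mean over all pooled-QC replicates across batches.
    ``cv_duplicates`` aggregates per-pair CVs over the technical duplicate
    pairs, by root-mean-square (default) or plain mean (``duplicate_cv=
    "mean"``). Missingness is computed over study samples only. Analytes with
    fewer than two pool replicates or no duplicate pairs get NaN for that
    metric (and will fail selection).
    """
    if duplicate_cv not in ("rms", "mean"):
        raise ConfigurationError("duplicate_cv must be 'rms' or 'mean'")
    df = dataset.measurements
    study = df[df["role"] == "study"]
    pool = df[df["role"] == "qc_pool"]
    by_id = df.set_index("sample_id")

    rows = {}
    for name in dataset.analytes:
        pvals = pool[name].dropna().to_numpy(dtype=float) if name in pool else np.array([])
        cv_pool = (
            100.0 * pvals.std(ddof=1) / pvals.mean() if pvals.size >= 2 else np.nan
        )
        pair_cvs = []
        for a, b in dataset.duplicate_pairs:
            va, vb = by_id.at[a, name], by_id.at[b, name]
            if np.isfinite(va) and np.isfinite(vb):
                pair_cvs.append(_pair_cv(float(va), float(vb)))
        if pair_cvs:
            pair_cvs = np.asarray(pair_cvs)
            cv_dup = (
                float(np.sqrt(np.mean(pair_cvs**2)))
                if duplicate_cv == "rms"
                else float(np.mean(pair_cvs))
            )
        else:
            cv_dup = np.nan
        missing = float(study[name].isna().mean()) if len(study) else np.nan
        rows[name] = {
            "missing_fraction": missing,
            "cv_pool": cv_pool,
            "cv_duplicates": cv_dup,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "analyte"
    table["selected"] = False
    table["exception_reason"] = ""
    return QCReport(table)


def select_assays(
    report: QCReport,
    cv_threshold: float = CV_THRESHOLD,
    missing_threshold: float = MISSING_THRESHOLD,
    missingness_exceptions: dict[str, str] | None = None,
    one_metric_exceptions: dict[str, str] | None = None,
) -> QCReport:
    """Apply the assay selection rule and record exceptions.

    An analyte is selected iff missing_fraction < missing_threshold (unless
    named in ``missingness_exceptions``) and both %CV metrics are <=
    cv_threshold; an analyte in ``one_metric_exceptions`` may fail exactly
    one of the two CV metrics. Exception dicts map analyte name -> reason.
    """
    missingness_exceptions = missingness_exceptions or {}
    one_metric_exceptions = one_metric_exceptions or {}
    t = report.table
    for name in list(missingness_exceptions) + list(one_metric_exceptions):
        if name not in t.index:
            raise ConfigurationError(f"exception names unknown analyte {name!r}")

    selected = []
    reasons = []
    for name, row in t.iterrows():
        reason = ""
        miss_ok = row["missing_fraction"] < missing_threshold
        if not miss_ok and name in missingness_exceptions:
            miss_ok = True
            reason = missingness_exceptions[name]
        cv_ok = [
            np.isfinite(row["cv_pool"]) and row["cv_pool"] <= cv_threshold,
            np.isfinite(row["cv_duplicates"]) and row["cv_duplicates"] <= cv_threshold,
        ]
        cvs_ok = all(cv_ok)
        if not cvs_ok and sum(cv_ok) == 1 and name in one_metric_exceptions:
            cvs_ok = True
            reason = (reason + "; " if reason else "") + one_metric_exceptions[name]
        selected.append(bool(miss_ok and cvs_ok))
        reasons.append(reason)
    out = QCReport(t.copy(), cv_threshold, missing_threshold)
    out.table["selected"] = selected
    out.table["exception_reason"] = reasons
    return out


# ---------------------------------------------------------------------------
# association screens
# ---------------------------------------------------------------------------


def screen_associations(
    table: pd.DataFrame,
    variable_types: dict[str, str],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Pairwise dependency screen with Bonferroni control.

    ``variable_types`` maps column -> {"categorical", "continuous"}. Test per
    pair: categorical x categorical -> chi-square; categorical (2 levels) x
    continuous -> Mann-Whitney U; categorical (>2 levels) x continuous ->
    Kruskal-Wallis; continuous x continuous -> Spearman. Constant variables
    are skipped with a reason. Returns a frame with raw and Bonferroni
    adjusted p-values and a ``flagged`` column (adjusted p < alpha).
    """
    names = list(variable_types)
    results = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            ta, tb = variable_types[a], variable_types[b]
            xa, xb = table[a], table[b]
            both = xa.notna() & xb.notna()
            xa, xb = xa[both], xb[both]
            row = {"var_a": a, "var_b": b, "test": None, "p": np.nan, "skipped": ""}
            if xa.nunique() < 2 or xb.nunique() < 2:
                row["skipped"] = "constant variable"
                results.append(row)
                continue
            if ta == "categorical" and tb == "categorical":
                ct = pd.crosstab(xa, xb)
                row["test"] = "chi-square"
                row["p"] = float(stats.chi2_contingency(ct)[1])
            elif ta == "categorical" or tb == "categorical":
                cat, cont = (xa, xb) if ta == "categorical" else (xb, xa)
                groups = [cont[cat == g].to_numpy(dtype=float) for g in cat.unique()]
                if len(groups) == 2:
                    row["test"] = "mann-whitney"
                    row["p"] = float(stats.mannwhitneyu(*groups, alternative="two-sided").pvalue)
                else:
                    row["test"] = "kruskal-wallis"
                    row["p"] = float(stats.kruskal(*groups).pvalue)
            else:
                row["test"] = "spearman"
                rho, p = stats.spearmanr(xa.to_numpy(dtype=float), xb.to_numpy(dtype=float))
                row["p"] = 0.0 if (abs(rho) == 1.0 and np.isnan(p)) else float(p)
            results.append(row)
    out = pd.DataFrame(results)
    n_tests = int(out["p"].notna().sum())
    out["p_adjusted"] = np.minimum(out["p"] * max(n_tests, 1), 1.0)
    out["flagged"] = out["p_adjusted"] < alpha
    return out


# ---------------------------------------------------------------------------
# model matrix
# ---------------------------------------------------------------------------


def collapse_duplicates(dataset: AssayDataset) -> pd.DataFrame:
    """Average each subject's study + duplicate measurements (post-scaling).

    Returns one row per subject with analyte values averaged over that
    subject's measurement events; QC pool rows are dropped. Non-analyte
    columns are taken from the study row.
    """
    df = dataset.measurements
    clinical = df[df["role"].isin(["study", "duplicate"])]
    meta_cols = [c for c in clinical.columns if c not in dataset.analytes]
    meta = clinical[clinical["role"] == "study"][meta_cols].set_index("subject_id")
    means = clinical.groupby("subject_id")[dataset.analytes].mean()
    out = meta.join(means).reset_index()
    return out.drop(columns=["sample_id", "role", "batch"], errors="ignore")


def prepare_model_matrix(
    table: pd.DataFrame,
    selected: list[str],
    log_transform: list[str] | None = None,
) -> pd.DataFrame:
    """Analysis-ready matrix: log-transformed analytes, complete cases.

    ``selected`` are the predictors retained for modelling; ``log_transform``
    defaults to all selected columns except MAP and BMI (biometric variables
    enter untransformed). Rows with any missing selected predictor are
    dropped; the count is recorded in ``attrs["n_dropped"]``. A non-positive
    value in a column to be logged raises, as it signals broken upstream
    scaling.
    """
    log_cols = (
        [c for c in selected if c not in ("MAP", "BMI")]
        if log_transform is None
        else list(log_transform)
    )
    out = table.copy()
    complete = out[selected].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    out = out[complete].reset_index(drop=True)
    for c in log_cols:
        vals = out[c].to_numpy(dtype=float)
        if (vals <= 0).any():
            raise DataError(f"non-positive value in {c!r} before log transform")
        out[c] = np.log(vals)
    out.attrs["n_dropped"] = n_dropped
    return out
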