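"""Synthetic cohort and nested case-control generator.

Emulates the statistical structure of a prospective pregnancy cohort with a
nested case-control metabolomics study: fixed outcome counts, analytes with
per-outcome effect sizes and AUROCs reproduced through an equal-variance
(log-)Gaussian calibration, inverse-sampling-fraction control weights, and
the technical structure of a batched LC-MS/MS campaign (batch effects,
pooled-QC replicates, technical duplicates, missingness).

The central identity: for two equal-variance Gaussians separated by
``delta_mu`` on the model scale, AUROC = Phi(delta_mu / (sigma * sqrt(2))).
Given a target median fold change FC (log-normal family, delta_mu = ln FC)
or median difference (normal family, delta_mu = difference) together with a
target AUROC, the common scale sigma = |delta_mu| / (sqrt(2) * Phi^-1(AUROC))
makes both targets hold simultaneously.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigurationError, InfeasibleCalibrationError, SamplingError

OUTCOMES = ("preterm_pe", "term_pe", "any_pe")
#: outcome labels used in cohort tables
LABEL_NONE = "none"
LABEL_PRETERM = "preterm_pe"
LABEL_TERM = "term_pe"

CENTRES = ("Cork", "Leeds", "London", "Manchester")
ETHNICITIES = ("white", "other")
WHITE_FRACTION = 0.95


# ---------------------------------------------------------------------------
# design and specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortDesign:
    """Fixed-count design of the cohort and its nested case-control study."""

    n_total: int = 2364
    n_preterm_pe: int = 23
    n_term_pe: int = 74
    n_controls_selected: int = 335

    def __post_init__(self) -> None:
        counts = (self.n_total, self.n_preterm_pe, self.n_term_pe, self.n_controls_selected)
        if any(c < 0 for c in counts):
            raise ConfigurationError("all design counts must be >= 0")
        if self.n_cases > self.n_total:
            raise ConfigurationError("case counts exceed cohort size")
        if self.n_controls_selected > self.n_non_pe:
            raise ConfigurationError("cannot select more controls than non-PE subjects")

    @property
    def n_cases(self) -> int:
        return self.n_preterm_pe + self.n_term_pe

    @property
    def n_non_pe(self) -> int:
        return self.n_total - self.n_cases

    @property
    def control_weight(self) -> float:
        """Inverse sampling fraction for selected controls."""
        return self.n_non_pe / self.n_controls_selected


@dataclass(frozen=True)
class OutcomeEffect:
    """Per-outcome targets: median effect and (folded) AUROC.

    ``effect`` is a median fold change for the log-normal family (direction
    down iff < 1) or a median difference for the normal family (direction
    down iff < 0).
    """

    effect: float
    auroc: float


@dataclass(frozen=True)
class Calibration:
    """Equal-variance two-Gaussian parameters on the model scale."""

    delta_mu: float
    sigma: float


@dataclass(frozen=True)
class BiomarkerSpec:
    """Generative description of one predictor variable.

    ``effects`` maps outcome names ("preterm_pe", "term_pe", "any_pe") to
    :class:`OutcomeEffect`; an outcome absent from the map means the variable
    has no predictive performance for it and cases of that subtype are drawn
    from the control distribution. ``control_location`` is the control median
    (log-normal) or control mean (normal). ``assayed`` marks analytes that go
    through the LC-MS/MS batch structure (batch effects, duplicates, QC pool,
    missingness); clinical covariates and externally assayed markers are not.
    """

    name: str
    family: str = "log-normal"  # or "normal"
    control_location: float = 1.0
    effects: dict[str, OutcomeEffect] = field(default_factory=dict)
    missing_rate: float = 0.05
    batch_effect_sd: float = 0.05
    technical_cv: float = 0.08
    assayed: bool = True
    null_sigma: float = 0.35  # model-scale sd when no outcome column calibrates it
    unit: str = "RC"

    def __post_init__(self) -> None:
        if self.family not in ("log-normal", "normal"):
            raise ConfigurationError(f"unknown family {self.family!r}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must be in [0, 1)")
        for outcome in self.effects:
            if outcome not in OUTCOMES:
                raise ConfigurationError(f"unknown outcome {outcome!r} in spec {self.name}")

    @property
    def neutral_effect(self) -> float:
        return 1.0 if self.family == "log-normal" else 0.0

    def calibration(self, outcome: str) -> Calibration | None:
        eff = self.effects.get(outcome)
        if eff is None:
            return None
        return calibrate_effect(eff.effect, eff.auroc, self.family)

    def control_sigma(self) -> float:
        """Model-scale sd of the control distribution.

        One control distribution has to serve every outcome; the preterm
        column's calibrated scale takes precedence, then term, then any-PE,
        then the null default.
        """
        for outcome in ("preterm_pe", "term_pe", "any_pe"):
            cal = self.calibration(outcome)
            if cal is not None:
                return cal.sigma
        return self.null_sigma

    @property
    def control_mu(self) -> float:
        if self.family == "log-normal":
            return math.log(self.control_location)
        return self.control_location


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


def calibrate_effect(effect_target: float, auroc_target: float, family: str = "log-normal") -> Calibration:
    """Joint calibration of a median effect and an AUROC target.

    Returns ``delta_mu`` (= ln FC for the log-normal family, = the median
    difference for the normal family) and the common scale
    ``sigma = |delta_mu| / (sqrt(2) * Phi^-1(auroc_target))`` such that cases
    ~ N(mu0 + delta_mu, sigma^2) and controls ~ N(mu0, sigma^2) on the model
    scale reproduce both targets.
    """
    if family == "log-normal":
        if effect_target <= 0:
            raise InfeasibleCalibrationError("fold change must be > 0")
        delta_mu = math.log(effect_target)
        neutral = effect_target == 1.0
    elif family == "normal":
        delta_mu = float(effect_target)
        neutral = effect_target == 0.0
    else:
        raise ConfigurationError(f"unknown family {family!r}")

    if auroc_target <= 0.5 and not neutral:
        raise InfeasibleCalibrationError(
            f"AUROC target {auroc_target} <= 0.5 with a non-neutral effect is infeasible"
        )
    if neutral:
        raise InfeasibleCalibrationError(
            "neutral effect: sigma is unidentifiable (null variable needs no calibration)"
        )
    if not auroc_target < 1.0:
        raise InfeasibleCalibrationError("AUROC target must be < 1")

    sigma = abs(delta_mu) / (math.sqrt(2.0) * norm.ppf(auroc_target))
    return Calibration(delta_mu=delta_mu, sigma=sigma)


def draw_calibrated(
    spec: BiomarkerSpec,
    outcome: str,
    n_cases: int,
    n_controls: int,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw case and control values under one outcome's own calibration.

    Both groups share that outcome's calibrated sigma, so the empirical AUROC
    and median effect converge to the spec targets. Values are returned on
    the original scale.
    """
    cal = spec.calibration(outcome)
    if cal is None:
        raise ConfigurationError(f"{spec.name} has no effect for outcome {outcome!r}")
    rng = np.random.default_rng(seed)
    mu0 = spec.control_mu
    cases = mu0 + cal.delta_mu + cal.sigma * rng.standard_normal(n_cases)
    controls = mu0 + cal.sigma * rng.standard_normal(n_controls)
    if spec.family == "log-normal":
        return np.exp(cases), np.exp(controls)
    return cases, controls


# ---------------------------------------------------------------------------
# default panel (printed design and effect sizes)
# ---------------------------------------------------------------------------


def default_biomarker_specs(n_null_metabolites: int = 36, seed: int = 20201228) -> list[BiomarkerSpec]:
    """The default paper-calibrated panel.

    Ten variables carry printed per-outcome (effect, AUROC) targets; the
    remaining metabolites of a 43-analyte panel are represented as null
    log-normal analytes so panel-level quantities (permutation FDR, screens)
    operate at a realistic width. Control locations for metabolites are
    relative concentrations around 1; PlGF is on an ng/mL scale with control
    median 0.040 so the clinically relevant low tail is well inside support.
    """
    oe = OutcomeEffect
    specs = [
        BiomarkerSpec(
            "MAP", family="normal", control_location=79.2,
            effects={"term_pe": oe(5.3, 0.69), "any_pe": oe(4.7, 0.67)},
            assayed=False, missing_rate=0.0, unit="mmHg",
        ),
        BiomarkerSpec(
            "BMI", family="normal", control_location=23.9,
            effects={"preterm_pe": oe(1.9, 0.65), "term_pe": oe(2.0, 0.63), "any_pe": oe(2.0, 0.64)},
            assayed=False, missing_rate=0.0, unit="kg/m2",
        ),
        BiomarkerSpec(
            "PlGF", control_location=0.040,
            effects={"preterm_pe": oe(0.43, 0.73), "any_pe": oe(0.71, 0.60)},
            assayed=False, missing_rate=0.0, unit="ng/mL",
        ),
        BiomarkerSpec(
            "DLG", effects={"preterm_pe": oe(1.45, 0.70), "any_pe": oe(1.23, 0.61)},
        ),
        BiomarkerSpec("choline", effects={"preterm_pe": oe(1.09, 0.61)}),
        BiomarkerSpec("isoleucine", effects={"term_pe": oe(1.12, 0.61)}),
        BiomarkerSpec(
            "1-HGP", effects={"term_pe": oe(0.89, 0.61), "any_pe": oe(0.89, 0.61)},
        ),
        BiomarkerSpec("2-hydroxybutanoate", effects={"preterm_pe": oe(1.16, 0.62)}),
        BiomarkerSpec("NG-monomethyl-L-arginine", effects={"preterm_pe": oe(1.08, 0.61)}),
        BiomarkerSpec("decanoylcarnitine", effects={"term_pe": oe(1.32, 0.60)}),
    ]
    rng = np.random.default_rng(seed)
    for i in range(n_null_metabolites):
        specs.append(
            BiomarkerSpec(
                f"null_met_{i + 1:02d}",
                control_location=float(np.round(np.exp(rng.uniform(-0.5, 1.5)), 3)),
                null_sigma=float(np.round(rng.uniform(0.2, 0.6), 3)),
            )
        )
    return specs


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def generate_cohort(
    design: CohortDesign,
    specs: list[BiomarkerSpec],
    seed: int,
) -> pd.DataFrame:
    """Generate a full cohort table with exactly the designed outcome counts.

    Counts are fixed by design (not binomial draws): the returned table has
    exactly ``design.n_preterm_pe`` preterm-PE, ``design.n_term_pe`` term-PE
    and ``design.n_non_pe`` unaffected subjects. Preterm and term cases are
    drawn from their outcome-specific case distributions; a variable with no
    effect for a subtype uses the control distribution for those cases.
    """
    if not specs:
        raise ConfigurationError("specs must be non-empty")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ConfigurationError("duplicate biomarker names in specs")

    rng = np.random.default_rng(seed)
    n = design.n_total
    outcome = np.array([LABEL_NONE] * n, dtype=object)
    idx = rng.permutation(n)
    outcome[idx[: design.n_preterm_pe]] = LABEL_PRETERM
    outcome[idx[design.n_preterm_pe : design.n_cases]] = LABEL_TERM

    table = pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:04d}" for i in range(n)],
            "outcome": outcome,
            "centre": rng.choice(CENTRES, size=n),
            "ethnicity": rng.choice(
                ETHNICITIES, size=n, p=(WHITE_FRACTION, 1.0 - WHITE_FRACTION)
            ),
        }
    )

    is_preterm = outcome == LABEL_PRETERM
    is_term = outcome == LABEL_TERM
    for spec in specs:
        sigma0 = spec.control_sigma()
        z = spec.control_mu + sigma0 * rng.standard_normal(n)
        for mask, oc in ((is_preterm, "preterm_pe"), (is_term, "term_pe")):
            cal = spec.calibration(oc)
            if cal is not None and mask.any():
                k = int(mask.sum())
                z[mask] = spec.control_mu + cal.delta_mu + cal.sigma * rng.standard_normal(k)
        table[spec.name] = np.exp(z) if spec.family == "log-normal" else z
    return table


def sample_case_control(
    cohort: pd.DataFrame, n_controls: int, seed: int
) -> pd.DataFrame:
    """Nested case-control sample: all cases plus random controls.

    Controls are sampled uniformly without replacement; each selected control
    carries weight (number of non-PE subjects in the cohort) / (controls
    selected) and each case carries weight 1, so weighted quantities are on
    the cohort scale.
    """
    is_case = cohort["outcome"] != LABEL_NONE
    controls = cohort.index[~is_case]
    if n_controls > len(controls):
        raise SamplingError(
            f"requested {n_controls} controls but only {len(controls)} non-PE subjects"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(controls.to_numpy(), size=n_controls, replace=False)
    out = pd.concat([cohort.loc[is_case], cohort.loc[np.sort(chosen)]], axis=0)
    out = out.reset_index(drop=True)
    out["weight"] = np.where(out["outcome"] != LABEL_NONE, 1.0, len(controls) / n_controls)
    return out


# ---------------------------------------------------------------------------
# technical structure
# ---------------------------------------------------------------------------


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class AssayDataset:
    """A cohort table wrapped with the technical structure of an assay run.

    ``measurements`` has one row per measurement event (roles: ``study``,
    ``duplicate``, ``qc_pool``) with analyte columns; masked cells are NaN.
    """

    measurements: pd.DataFrame
    analytes: list[str]
    duplicate_pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        ids = set(self.measurements["sample_id"])
        for a, b in self.duplicate_pairs:
            if a not in ids or b not in ids:
                raise ConfigurationError(f"duplicate pair ({a}, {b}) references missing samples")
        qc = self.measurements[self.measurements["role"] == "qc_pool"]
        study = self.measurements[self.measurements["role"] == "study"]
        if len(study) and len(qc):
            missing_qc = set(study["batch"]) - set(qc["batch"])
            if missing_qc:
                raise ConfigurationError(f"batches without QC pool records: {sorted(missing_qc)}")

    @property
    def study(self) -> pd.DataFrame:
        return self.measurements[self.measurements["role"] == "study"]

    @property
    def qc_pool(self) -> pd.DataFrame:
        return self.measurements[self.measurements["role"] == "qc_pool"]

    def copy(self) -> "AssayDataset":
        return AssayDataset(
            self.measurements.copy(), list(self.analytes), list(self.duplicate_pairs)
        )


def _stratified_batches(meta: pd.DataFrame, n_batches: int, rng: np.random.Generator) -> np.ndarray:
    """Stratified randomisation of measurement events over batches.

    Strata are centre x ethnicity x PE status; within each stratum the events
    are shuffled and dealt round-robin over a rotating batch order, which
    balances batch sizes even when strata are small.
    """
    batch = np.empty(len(meta), dtype=int)
    strata = meta.groupby(
        [meta["centre"], meta["ethnicity"], meta["outcome"] != LABEL_NONE], sort=True
    ).indices
    offset = 0
    for key in sorted(strata, key=str):
        rows = np.asarray(strata[key])
        rng.shuffle(rows)
        for j, r in enumerate(rows):
            batch[r] = (offset + j) % n_batches
        offset += len(rows)
    return batch


def inject_technical_structure(
    cohort: pd.DataFrame,
    specs: list[BiomarkerSpec],
    n_batches: int = 6,
    dup_fraction: float = 0.15,
    qc_replicates_per_batch: int = 9,
    seed: int = 0,
) -> AssayDataset:
    """Wrap a cohort (or case-control) table into a simulated assay campaign.

    Assayed analytes receive per-batch multiplicative effects
    ``exp(N(0, batch_effect_sd))``, multiplicative technical noise
    ``exp(N(0, technical_cv))`` on every measurement event, pooled-QC
    replicates per batch, technical duplicates for ``dup_fraction`` of the
    study samples (count rounded half up) and missing cells at each analyte's
    missing rate. Non-assayed variables are carried through untouched.
    """
    if not 0.0 <= dup_fraction <= 1.0:
        raise ConfigurationError("dup_fraction must be in [0, 1]")
    if n_batches < 1:
        raise ConfigurationError("need at least one batch")
    rng = np.random.default_rng(seed)
    specs = [s for s in specs if s.name in cohort.columns]
    assayed = [s for s in specs if s.assayed]

    study = cohort.copy().reset_index(drop=True)
    study["sample_id"] = study["subject_id"] + "_m1"
    study["role"] = "study"

    n_dup = _round_half_up(dup_fraction * len(study))
    dup_rows = rng.choice(len(study), size=n_dup, replace=False)
    dup = study.iloc[np.sort(dup_rows)].copy()
    dup["sample_id"] = dup["subject_id"] + "_m2"
    dup["role"] = "duplicate"
    pairs = list(zip(dup["subject_id"] + "_m1", dup["sample_id"]))

    events = pd.concat([study, dup], ignore_index=True)
    events["batch"] = _stratified_batches(events, n_batches, rng)

    qc_frames = []
    for b in range(n_batches):
        qcf = pd.DataFrame(
            {
                "sample_id": [f"QCpool_b{b}_r{r + 1}" for r in range(qc_replicates_per_batch)],
                "subject_id": "QCpool",
                "role": "qc_pool",
                "batch": b,
                "outcome": LABEL_NONE,
                "centre": "pool",
                "ethnicity": "pool",
            }
        )
        for spec in assayed:
            qcf[spec.name] = spec.control_location  # pool = pooled study material
        qc_frames.append(qcf)
    events = pd.concat([events] + qc_frames, ignore_index=True)

    for spec in assayed:
        factors = np.exp(rng.normal(0.0, spec.batch_effect_sd, size=n_batches))
        vals = events[spec.name].to_numpy(dtype=float)
        vals = vals * factors[events["batch"].to_numpy()]
        vals = vals * np.exp(rng.normal(0.0, spec.technical_cv, size=len(events)))
        clinical = events["role"] != "qc_pool"
        if spec.missing_rate > 0:
            miss = (rng.random(len(events)) < spec.missing_rate) & clinical
            vals[miss] = np.nan
        events[spec.name] = vals

    cols = ["sample_id", "subject_id", "role", "batch", "outcome", "centre", "ethnicity"]
    other = [c for c in cohort.columns if c not in cols and c not in [s.name for s in specs]]
    ordered = cols + [c for c in other if c != "subject_id"] + [s.name for s in specs]
    events = events[[c for c in ordered if c in events.columns]]
    return AssayDataset(events, [s.name for s in specs], pairs)


def default_dataset(
    seed: int = 1,
    design: CohortDesign | None = None,
    specs: list[BiomarkerSpec] | None = None,
    with_technical: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, AssayDataset | None, list[BiomarkerSpec]]:
    """Convenience: cohort, case-control table and assay dataset at defaults.

    Child seeds for the three stages are spawned from ``seed`` so any stage
    is individually reproducible.
    """
    design = design or CohortDesign()
    specs = specs if specs is not None else default_biomarker_specs()
    s1, s2, s3 = np.random.SeedSequence(seed).generate_state(3) % (2**31)
    cohort = generate_cohort(design, specs, int(s1))
    cc = sample_case_control(cohort, design.n_controls_selected, int(s2))
    assay = inject_technical_structure(cc, specs, seed=int(s3)) if with_technical else None
    return cohort, cc, assay, specs


def write_cohort_csv(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, index=False)


def read_cohort_csv(path: str) -> pd.DataFrame:
    return pd.read_csv(path)
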