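"""Univariable predictor pre-selection.

AUROC by the Mann-Whitney rank statistic with a DeLong confidence interval,
median effect sizes (difference or fold change) with stratified percentile
bootstrap CIs, the selection rule (AUROC > 0.60 with a lower 95% CI bound
>= 0.50), and panel-level false discovery rates by outcome-label permutation
with a conservative pi0 = 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigurationError, DataError
from .synthcohort import LABEL_NONE, LABEL_PRETERM, LABEL_TERM

AUROC_FLOOR = 0.60
CI_LOW_FLOOR = 0.50


def outcome_mask(outcomes: pd.Series | np.ndarray, outcome: str) -> tuple[np.ndarray, np.ndarray]:
    """(case, control) boolean masks for one outcome definition.

    Each subtype outcome compares its cases against non-PE controls (the
    other subtype's cases are excluded); ``any_pe`` pools both subtypes.
    """
    oc = np.asarray(outcomes)
    if outcome == "preterm_pe":
        return oc == LABEL_PRETERM, oc == LABEL_NONE
    if outcome == "term_pe":
        return oc == LABEL_TERM, oc == LABEL_NONE
    if outcome == "any_pe":
        return (oc == LABEL_PRETERM) | (oc == LABEL_TERM), oc == LABEL_NONE
    raise ConfigurationError(f"unknown outcome {outcome!r}")


# ---------------------------------------------------------------------------
# AUROC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AurocResult:
    auroc: float  # folded so >= 0.5
    ci_low: float
    ci_high: float
    direction: str  # "up" if cases tend higher, else "down"
    degenerate: bool = False


def _auroc_raw(cases: np.ndarray, controls: np.ndarray) -> float:
    """P(case > control) + 0.5 P(tie), via searchsorted on sorted controls."""
    sc = np.sort(controls)
    below = np.searchsorted(sc, cases, side="left")
    below_or_eq = np.searchsorted(sc, cases, side="right")
    return float((below + 0.5 * (below_or_eq - below)).sum() / (len(cases) * len(controls)))


def _delong_variance(cases: np.ndarray, controls: np.ndarray) -> float:
    """DeLong variance of the AUROC via structural components."""
    m, n = len(cases), len(controls)
    sc = np.sort(controls)
    v10 = (
        np.searchsorted(sc, cases, side="left")
        + 0.5 * (np.searchsorted(sc, cases, side="right") - np.searchsorted(sc, cases, side="left"))
    ) / n
    scs = np.sort(cases)
    above = m - np.searchsorted(scs, controls, side="right")
    ties = np.searchsorted(scs, controls, side="right") - np.searchsorted(scs, controls, side="left")
    v01 = (above + 0.5 * ties) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def estimate_auroc(
    values: np.ndarray, case: np.ndarray, alpha: float = 0.05
) -> AurocResult:
    """Rank-statistic AUROC with a DeLong 95% CI, folded to >= 0.5.

    Ties count one half. Orientation is folded so the reported AUROC is at
    least 0.5 and the natural direction ("up": cases higher) is recorded;
    the CI is computed on the folded statistic. All-tied input yields AUROC
    0.5 with a degenerate CI flag.
    """
    values = np.asarray(values, dtype=float)
    case = np.asarray(case, dtype=bool)
    if np.isnan(values).any():
        keep = ~np.isnan(values)
        values, case = values[keep], case[keep]
    cases, controls = values[case], values[~case]
    if len(cases) == 0 or len(controls) == 0:
        raise DataError("both classes must be present to estimate an AUROC")
    a = _auroc_raw(cases, controls)
    direction = "up" if a >= 0.5 else "down"
    folded = max(a, 1.0 - a)
    var = _delong_variance(cases, controls)
    if var == 0.0 and folded == 0.5:
        return AurocResult(0.5, 0.5, 0.5, direction, degenerate=True)
    half = norm.ppf(1.0 - alpha / 2.0) * np.sqrt(var)
    return AurocResult(
        folded,
        float(max(0.0, folded - half)),
        float(min(1.0, folded + half)),
        direction,
        degenerate=var == 0.0,
    )


# ---------------------------------------------------------------------------
# effect sizes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EffectResult:
    effect: float
    ci_low: float
    ci_high: float
    kind: str  # "difference" or "fold-change"


def estimate_effect(
    values: np.ndarray,
    case: np.ndarray,
    kind: str = "fold-change",
    B_boot: int = 2000,
    seed: int = 0,
) -> EffectResult:
    """Median effect on the original scale with a stratified bootstrap CI.

    ``difference``: median(cases) - median(controls); ``fold-change``:
    median(cases) / median(controls). The percentile 95% CI resamples cases
    and controls separately.
    """
    if kind not in ("difference", "fold-change"):
        raise ConfigurationError("kind must be 'difference' or 'fold-change'")
    values = np.asarray(values, dtype=float)
    case = np.asarray(case, dtype=bool)
    keep = ~np.isnan(values)
    values, case = values[keep], case[keep]
    cases, controls = values[case], values[~case]
    if len(cases) == 0 or len(controls) == 0:
        raise DataError("both classes must be present to estimate an effect")

    def point(cs: np.ndarray, ct: np.ndarray) -> float:
        mc, m0 = np.median(cs), np.median(ct)
        if kind == "difference":
            return float(mc - m0)
        if m0 == 0:
            raise DataError("zero control median: fold change undefined")
        return float(mc / m0)

    est = point(cases, controls)
    rng = np.random.default_rng(seed)
    reps = np.empty(B_boot)
    for b in range(B_boot):
        reps[b] = point(
            rng.choice(cases, size=len(cases), replace=True),
            rng.choice(controls, size=len(controls), replace=True),
        )
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return EffectResult(est, float(lo), float(hi), kind)


# ---------------------------------------------------------------------------
# report and selection rule
# ---------------------------------------------------------------------------


def passes_selection(auroc: float, ci_low: float) -> bool:
    """Strict > 0.60 on the AUROC, inclusive >= 0.50 on its lower CI bound."""
    return auroc > AUROC_FLOOR and ci_low >= CI_LOW_FLOOR


@dataclass
class PredictorReport:
    """Per variable x outcome univariable summary (Table-2-shaped)."""

    table: pd.DataFrame  # cols: variable, outcome, auroc, ci_low, ci_high, effect, effect_ci_low, effect_ci_high, kind, direction, selected
    fdr: dict[str, float]

    def selected(self, outcome: str) -> list[str]:
        t = self.table
        return list(t.loc[(t["outcome"] == outcome) & t["selected"], "variable"])

    @property
    def modelling_set(self) -> list[str]:
        """Variables carried to modelling: those selected for any-PE."""
        return self.selected("any_pe")

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, index=False)


def build_predictor_report(
    table: pd.DataFrame,
    variables: list[str],
    effect_kinds: dict[str, str] | None = None,
    outcomes: tuple[str, ...] = ("preterm_pe", "term_pe", "any_pe"),
    B_boot: int = 2000,
    B_perm: int = 2000,
    pi0: float = 1.0,
    seed: int = 0,
    with_fdr: bool = True,
) -> PredictorReport:
    """Univariable AUROCs, effects and selection flags for a variable panel.

    ``effect_kinds`` maps variable -> "difference"/"fold-change"; defaults to
    difference for MAP and BMI, fold change otherwise. Values are used on the
    scale given (effects are meant to be computed pre-log).
    """
    effect_kinds = effect_kinds or {}
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(len(variables) * len(outcomes) + len(outcomes)) % (2**31)
    rows = []
    si = 0
    for outcome in outcomes:
        case, control = outcome_mask(table["outcome"], outcome)
        include = case | control
        for var in variables:
            vals = table.loc[include, var].to_numpy(dtype=float)
            cs = case[include]
            ar = estimate_auroc(vals, cs)
            kind = effect_kinds.get(var, "difference" if var in ("MAP", "BMI") else "fold-change")
            er = estimate_effect(vals, cs, kind=kind, B_boot=B_boot, seed=int(seeds[si]))
            si += 1
            rows.append(
                {
                    "variable": var,
                    "outcome": outcome,
                    "auroc": ar.auroc,
                    "ci_low": ar.ci_low,
                    "ci_high": ar.ci_high,
                    "effect": er.effect,
                    "effect_ci_low": er.ci_low,
                    "effect_ci_high": er.ci_high,
                    "kind": kind,
                    "direction": ar.direction,
                    "selected": passes_selection(ar.auroc, ar.ci_low),
                }
            )
    report = pd.DataFrame(rows)
    fdr = {}
    if with_fdr:
        for j, outcome in enumerate(outcomes):
            fdr[outcome] = estimate_fdr_permutation(
                table, variables, outcome, B=B_perm, pi0=pi0, seed=int(seeds[si + j])
            )
    return PredictorReport(report, fdr)


# ---------------------------------------------------------------------------
# permutation FDR
# ---------------------------------------------------------------------------


def _count_discoveries(values: np.ndarray, case: np.ndarray) -> int:
    """Number of variables (columns) passing the selection rule."""
    n = 0
    for j in range(values.shape[1]):
        r = estimate_auroc(values[:, j], case)
        n += passes_selection(r.auroc, r.ci_low)
    return n


def estimate_fdr_permutation(
    table: pd.DataFrame,
    variables: list[str],
    outcome: str,
    B: int = 20000,
    pi0: float = 1.0,
    seed: int = 0,
    exact: bool = False,
) -> float:
    """Panel-level FDR of the selection rule by outcome-label permutation.

    Estimate = pi0 * E[#discoveries under permuted labels] / #observed
    discoveries, capped at 1. Labels are permuted jointly across all
    variables per replicate, preserving the inter-variable correlation.
    ``exact=True`` enumerates every distinct case/control labelling instead
    of sampling B of them (only sensible for tiny inputs). Zero observed
    discoveries yields NaN.
    """
    case, control = outcome_mask(table["outcome"], outcome)
    include = case | control
    values = table.loc[include, variables].to_numpy(dtype=float)
    cs = case[include]
    observed = _count_discoveries(values, cs)
    if observed == 0:
        return float("nan")

    n, k = len(cs), int(cs.sum())
    if exact:
        total = 0
        count = 0
        for pos in combinations(range(n), k):
            perm = np.zeros(n, dtype=bool)
            perm[list(pos)] = True
            total += _count_discoveries(values, perm)
            count += 1
        null_mean = total / count
    else:
        if B < 1:
            raise ConfigurationError("B must be >= 1")
        rng = np.random.default_rng(seed)
        total = 0
        for _ in range(B):
            total += _count_discoveries(values, rng.permutation(cs))
        null_mean = total / B
    return float(min(1.0, pi0 * null_mean / observed))
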