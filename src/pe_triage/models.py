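"""Classifier construction.

Two model families are fitted on the analysis-ready (log-scale) matrix:

* PLS-DA score models on 1-3 predictors, standardized, class encoded +/-1,
  oriented so a higher score means higher PE risk;
* recursive-partitioning models with PlGF imposed as the first partition
  step, one or two predictors per step (two-predictor steps score through a
  PLS-DA trained on the high-PlGF subgroup), and cut-offs selected to
  maximize sensitivity (rule-in) or specificity (rule-out) subject to a
  weighted PPV or NPV floor on the final model.

A subject flagged at any step exits with the positive call; the terminal
default is negative, so the final positive set is the union of the per-step
risky tails. Because step scores do not depend on earlier cut-offs, cut-offs
interact only through that union, which makes a joint search over a
candidate grid exact and cheap for the 2-3 partitions used here; a greedy
per-step search is available as an alternative.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .errors import ConfigurationError, DataError

#: side of each predictor associated with PE risk (from univariable directions)
RISK_DIRECTION = {"PlGF": "down", "DLG": "up", "1-HGP": "down", "MAP": "up", "BMI": "up"}

PLGF = "PlGF"


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------


@dataclass
class PLSDAModel:
    """A fitted PLS-DA scorer: continuous risk score, higher = riskier."""

    predictors: list[str]
    n_components: int
    x_mean: np.ndarray
    x_std: np.ndarray
    coef: np.ndarray  # score = (x - mean)/std @ coef  (orientation applied)
    x_weights: np.ndarray
    orientation: float = 1.0

    def score(self, table: pd.DataFrame) -> np.ndarray:
        x = table[self.predictors].to_numpy(dtype=float)
        return ((x - self.x_mean) / self.x_std) @ self.coef

    def to_dict(self) -> dict:
        return {
            "predictors": self.predictors,
            "n_components": self.n_components,
            "x_mean": self.x_mean.tolist(),
            "x_std": self.x_std.tolist(),
            "coef": self.coef.tolist(),
            "orientation": self.orientation,
        }


def fit_plsda(
    table: pd.DataFrame,
    predictors: list[str],
    labels: np.ndarray,
    n_components: int | None = None,
) -> PLSDAModel:
    """Fit a PLS-DA model on complete cases.

    Predictors are standardized on the training data and the class encoded
    +/-1; the returned model's score is the PLS regression prediction, a
    linear function of the standardized predictors, sign-fixed so cases
    score higher. Constant predictors are dropped with a warning; the
    component count defaults to min(2, #predictors) and is reduced to the
    feasible rank if necessary.
    """
    labels = np.asarray(labels, dtype=bool)
    x = table[predictors].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise DataError("PLS-DA requires complete cases")
    keep = [i for i in range(x.shape[1]) if x[:, i].std() > 0]
    if len(keep) < len(predictors):
        dropped = [p for i, p in enumerate(predictors) if i not in keep]
        warnings.warn(f"constant predictors dropped: {dropped}")
    if not keep:
        raise DataError("no non-constant predictors")
    predictors = [predictors[i] for i in keep]
    x = x[:, keep]
    if n_components is None:
        n_components = min(2, x.shape[1])
    n_components = min(n_components, x.shape[1], len(x) - 1)
    y = np.where(labels, 1.0, -1.0)

    pls = PLSRegression(n_components=n_components, scale=False)
    mean, std = x.mean(axis=0), x.std(axis=0, ddof=1)
    pls.fit((x - mean) / std, y)
    coef = pls.coef_.ravel()
    model = PLSDAModel(
        predictors=predictors,
        n_components=n_components,
        x_mean=mean,
        x_std=std,
        coef=coef,
        x_weights=pls.x_weights_,
    )
    score = model.score(table)
    # orient: higher score = cases
    if np.mean(score[labels]) < np.mean(score[~labels]):
        model.coef = -model.coef
        model.orientation = -1.0
    return model


# ---------------------------------------------------------------------------
# high-PlGF subgroup threshold
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HighPlGFThreshold:
    """Accuracy-maximizing PlGF split; the high subgroup is >= threshold."""

    threshold: float
    accuracy: float
    degenerate: bool = False


def find_high_plgf_threshold(plgf: np.ndarray, labels: np.ndarray) -> HighPlGFThreshold:
    """Scan observed PlGF values for the accuracy-maximizing cut-off.

    Subjects with PlGF below the cut-off are classified as PE; the returned
    threshold is the observed value maximizing unweighted accuracy, ties
    broken toward the smaller threshold (the larger retained high-PlGF
    subgroup). If no split beats the trivial majority classifier, the result
    is flagged degenerate.
    """
    plgf = np.asarray(plgf, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or (~labels).all():
        raise DataError("both classes required")
    n = len(plgf)
    candidates = np.concatenate([np.unique(plgf), [np.inf]])
    best_t, best_acc = np.inf, -1.0
    for t in candidates:
        low = plgf < t
        acc = (low == labels).sum() / n
        if acc > best_acc:
            best_acc, best_t = acc, t
    majority = max(labels.mean(), 1.0 - labels.mean())
    return HighPlGFThreshold(float(best_t), float(best_acc), degenerate=best_acc <= majority)


# ---------------------------------------------------------------------------
# partition models
# ---------------------------------------------------------------------------


@dataclass
class PartitionStep:
    """One partition: a score, a risky direction and a cut-off.

    ``cutoff`` None means the step flags nobody (it was skipped). For
    direction "up" the step flags score >= cutoff, for "down" score <=
    cutoff; flagged subjects exit with the positive call.
    """

    predictors: list[str]
    direction: str
    cutoff: float | None
    scorer: PLSDAModel | None = None  # None: identity on the single predictor

    def score(self, table: pd.DataFrame) -> np.ndarray:
        if self.scorer is not None:
            return self.scorer.score(table)
        return table[self.predictors[0]].to_numpy(dtype=float)

    def flags(self, score: np.ndarray) -> np.ndarray:
        if self.cutoff is None:
            return np.zeros(len(score), dtype=bool)
        if self.direction == "up":
            return score >= self.cutoff
        return score <= self.cutoff

    def to_dict(self) -> dict:
        return {
            "predictors": self.predictors,
            "direction": self.direction,
            "cutoff": self.cutoff,
            "plsda": self.scorer.to_dict() if self.scorer else None,
        }


@dataclass
class PartitionModel:
    """Ordered PlGF-first partition steps with a predictive-value objective."""

    steps: list[PartitionStep]
    objective: str  # "rule-in" or "rule-out"
    pv_target: float
    feasible: bool = True
    reason: str = ""
    high_plgf: HighPlGFThreshold | None = None
    training_metrics: dict = field(default_factory=dict)

    def predict(self, table: pd.DataFrame) -> pd.DataFrame:
        """Per-subject flag and step-of-decision (0 = terminal default).

        Subjects missing any needed predictor are unclassifiable: flag NaN,
        step -1.
        """
        n = len(table)
        flag = np.zeros(n, dtype=float)
        step_of = np.zeros(n, dtype=int)
        remaining = np.ones(n, dtype=bool)
        for k, step in enumerate(self.steps, start=1):
            missing = table[step.predictors].isna().any(axis=1).to_numpy()
            bad = remaining & missing
            flag[bad], step_of[bad] = np.nan, -1
            remaining &= ~missing
            score = step.score(table[step.predictors].fillna(0.0))
            hit = remaining & step.flags(score)
            flag[hit], step_of[hit] = 1.0, k
            remaining &= ~hit
        return pd.DataFrame({"flag": flag, "step": step_of}, index=table.index)

    def flags(self, table: pd.DataFrame) -> np.ndarray:
        pred = self.predict(table)
        if pred["flag"].isna().any():
            raise DataError("unclassifiable subjects (missing predictors)")
        return pred["flag"].to_numpy() == 1.0

    def to_json(self, path: str) -> None:
        payload = {
            "objective": self.objective,
            "pv_target": self.pv_target,
            "feasible": self.feasible,
            "reason": self.reason,
            "steps": [s.to_dict() for s in self.steps],
            "training_metrics": self.training_metrics,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _risk_direction(name: str, values: np.ndarray, labels: np.ndarray) -> str:
    if name in RISK_DIRECTION:
        return RISK_DIRECTION[name]
    return "up" if np.median(values[labels]) >= np.median(values[~labels]) else "down"


def _candidates(score: np.ndarray, max_grid: int | None) -> np.ndarray:
    """Candidate cut-offs: observed values, quantile-gridded when many.

    When gridding, the extreme eight values of each tail are always kept so
    small, pure flag sets (where predictive-value constraints bind) stay
    reachable.
    """
    vals = np.unique(score)
    if max_grid is not None and len(vals) > max_grid:
        qs = np.linspace(0.0, 1.0, max(max_grid - 16, 2))
        grid = np.quantile(vals, qs, method="nearest")
        vals = np.unique(np.concatenate([vals[:8], grid, vals[-8:]]))
    return vals


def _constraint_and_objective(
    objective: str,
) -> tuple[str, str]:
    if objective == "rule-in":
        return "ppv", "sensitivity"
    if objective == "rule-out":
        return "npv", "specificity"
    raise ConfigurationError("objective must be 'rule-in' or 'rule-out'")


def _evaluate_combo(
    flag: np.ndarray, wcase: np.ndarray, wctrl: np.ndarray
) -> tuple[float, float, float, float]:
    """(ppv, npv, sensitivity, specificity) from weighted case/control masses."""
    tp = float(wcase[flag].sum())
    fp = float(wctrl[flag].sum())
    fn = float(wcase[~flag].sum())
    tn = float(wctrl[~flag].sum())
    ppv = tp / (tp + fp) if tp + fp > 0 else np.nan
    npv = tn / (tn + fn) if tn + fn > 0 else np.nan
    return ppv, npv, tp / (tp + fn), tn / (tn + fp)


def build_partition_model(
    table: pd.DataFrame,
    labels: np.ndarray,
    objective: str,
    steps: list[list[str]],
    weights: np.ndarray | None = None,
    pv_target: float = 0.05,
    search: str = "auto",
    max_grid: int | None = None,
    subgroup_labels: np.ndarray | None = None,
    two_pred_subgroup: bool = True,
    plgf_col: str = PLGF,
) -> PartitionModel:
    """Fit a PlGF-first partition model under a predictive-value constraint.

    ``steps`` lists the predictor set of each partition (1 or 2 names, PlGF
    alone first). Cut-offs are selected to maximize weighted sensitivity
    (rule-in) or specificity (rule-out) subject to the final model's
    weighted PPV (rule-in) or NPV (rule-out) >= ``pv_target``. ``search``:
    "exhaustive" scans the joint candidate grid (exact on the grid; the grid
    is every observed value when a step has <= ``max_grid`` distinct
    scores), "greedy" fits cut-offs sequentially, "auto" = exhaustive.
    Two-predictor steps are scored by a PLS-DA trained on the high-PlGF
    subgroup (threshold from accuracy-maximizing scan against
    ``subgroup_labels``, default the model's own labels). If no cut-off
    combination satisfies the constraint the model is returned with
    ``feasible=False``; an infeasible use case is a first-class result.
    """
    labels = np.asarray(labels, dtype=bool)
    w = np.ones(len(labels)) if weights is None else np.asarray(weights, dtype=float)
    if not steps:
        raise ConfigurationError("at least one partition step required")
    if steps[0] != [plgf_col]:
        raise ConfigurationError(f"first partition step must be [{plgf_col!r}]")
    if any(len(s) not in (1, 2) for s in steps):
        raise ConfigurationError("each step uses one or two predictors")
    distinct = {p for s in steps for p in s}
    if len(distinct) > 3:
        raise ConfigurationError("at most three distinct predictors")
    constraint_name, objective_name = _constraint_and_objective(objective)

    high = None
    fitted_steps: list[PartitionStep] = []
    for spec in steps:
        if len(spec) == 1:
            vals = table[spec[0]].to_numpy(dtype=float)
            fitted_steps.append(
                PartitionStep(spec, _risk_direction(spec[0], vals, labels), None)
            )
        else:
            if two_pred_subgroup:
                sub_labels = labels if subgroup_labels is None else np.asarray(subgroup_labels, bool)
                if high is None:
                    high = find_high_plgf_threshold(
                        table[plgf_col].to_numpy(dtype=float), sub_labels
                    )
                mask = table[plgf_col].to_numpy(dtype=float) >= high.threshold
                if mask.sum() < 3 or labels[mask].all() or (~labels[mask]).all():
                    mask = np.ones(len(table), dtype=bool)  # subgroup too degenerate
                scorer = fit_plsda(table[mask], spec, labels[mask])
            else:
                scorer = fit_plsda(table, spec, labels)
            fitted_steps.append(PartitionStep(spec, "up", None, scorer))

    scores = [s.score(table) for s in fitted_steps]
    if max_grid is None:
        # budget the joint grid: full resolution for 1-2 steps at this n,
        # ~55 quantile candidates per step for 3 steps
        max_grid = max(33, int(round(160_000 ** (1.0 / len(steps)))))
    cand = [_candidates(sc, max_grid) for sc in scores]
    wcase, wctrl = w * labels, w * (~labels)

    if search in ("auto", "exhaustive"):
        chosen = _search_exhaustive(
            fitted_steps, scores, cand, wcase, wctrl, pv_target, constraint_name, objective_name
        )
    elif search == "greedy":
        chosen = _search_greedy(
            fitted_steps, scores, cand, wcase, wctrl, pv_target, constraint_name, objective_name
        )
    else:
        raise ConfigurationError("search must be 'auto', 'exhaustive' or 'greedy'")

    model = PartitionModel(
        steps=fitted_steps, objective=objective, pv_target=pv_target, high_plgf=high
    )
    if chosen is None:
        model.feasible = False
        model.reason = (
            f"no cut-off combination reaches weighted {constraint_name} >= {pv_target}"
        )
        for s in fitted_steps:
            s.cutoff = None
        return model
    for s, c in zip(fitted_steps, chosen):
        s.cutoff = c
    flag = np.zeros(len(table), dtype=bool)
    for s, sc in zip(fitted_steps, scores):
        flag |= s.flags(sc)
    ppv, npv, sens, spec = _evaluate_combo(flag, wcase, wctrl)
    model.training_metrics = {
        "ppv": ppv, "npv": npv, "sensitivity": sens, "specificity": spec,
    }
    return model


def _combo_key(
    ppv: float, npv: float, sens: float, spec: float, n_flag: float,
    pv_target: float, constraint_name: str, objective_name: str,
) -> tuple | None:
    vals = {"ppv": ppv, "npv": npv, "sensitivity": sens, "specificity": spec}
    c = vals[constraint_name]
    if pv_target > 0:
        if np.isnan(c) or c < pv_target:
            return None
    cv = 1.0 if np.isnan(c) else c
    return (vals[objective_name], cv, -n_flag)


def _search_exhaustive(steps, scores, cand, wcase, wctrl, pv_target, cname, oname):
    """Joint scan over the candidate grid; exact given the grid.

    Candidate lists get a leading None sentinel (step flags nobody). The
    union structure of the flags makes every combination evaluable from the
    per-step tail masks.
    """
    tails = []
    for step, sc, cd in zip(steps, scores, cand):
        mats = [np.zeros(len(sc), dtype=bool)]  # sentinel: flag none
        for c in cd:
            mats.append(sc >= c if step.direction == "up" else sc <= c)
        tails.append(np.column_stack(mats))
    cut_lists = [np.concatenate([[np.nan], cd]) for cd in cand]

    best_key, best_combo = None, None

    def rec(k: int, flag: np.ndarray, chosen: list[int]):
        nonlocal best_key, best_combo
        if k == len(tails) - 1:
            fl = flag[:, None] | tails[k]
            tp = wcase @ fl
            fp = wctrl @ fl
            fn = wcase @ ~fl  # complement sums: exact zeros for empty sets
            tn = wctrl @ ~fl
            with np.errstate(invalid="ignore", divide="ignore"):
                ppv = np.where(tp + fp > 0, tp / (tp + fp), np.nan)
                npv = np.where(tn + fn > 0, tn / (tn + fn), np.nan)
            sens, spec = tp / (tp + fn), tn / (tn + fp)
            nfl = fl.sum(axis=0)
            for i in range(fl.shape[1]):
                key = _combo_key(
                    ppv[i], npv[i], sens[i], spec[i], nfl[i], pv_target, cname, oname
                )
                if key is not None and (best_key is None or key > best_key):
                    best_key, best_combo = key, chosen + [i]
            return
        for i in range(tails[k].shape[1]):
            rec(k + 1, flag | tails[k][:, i], chosen + [i])

    rec(0, np.zeros(len(wcase), dtype=bool), [])
    if best_combo is None:
        return None
    return [
        None if np.isnan(cut_lists[k][i]) else float(cut_lists[k][i])
        for k, i in enumerate(best_combo)
    ]


def _search_greedy(steps, scores, cand, wcase, wctrl, pv_target, cname, oname):
    """Sequential cut-off selection, constraint on the provisional model.

    At each step every candidate (plus the flag-none sentinel) is scored by
    the model built so far with later steps flagging nobody; the best
    feasible candidate by objective wins. When no candidate is feasible the
    step either stays at the sentinel (rule-in) or takes the candidate that
    maximizes the constraint metric (rule-out, progress toward the NPV
    floor). Infeasible overall if the final model misses the constraint.
    """
    flag = np.zeros(len(wcase), dtype=bool)
    chosen: list[float | None] = []
    for step, sc, cd in zip(steps, scores, cand):
        options: list[tuple[float | None, np.ndarray]] = [(None, flag)]
        for c in cd:
            tail = sc >= c if step.direction == "up" else sc <= c
            options.append((float(c), flag | tail))
        best_key, best = None, None
        fallback_key, fallback = None, None
        for c, fl in options:
            ppv, npv, sens, spec = _evaluate_combo(fl, wcase, wctrl)
            key = _combo_key(ppv, npv, sens, spec, fl.sum(), pv_target, cname, oname)
            if key is not None and (best_key is None or key > best_key):
                best_key, best = key, (c, fl)
            cval = {"ppv": ppv, "npv": npv}.get(cname, np.nan)
            fkey = (-1.0 if np.isnan(cval) else cval, {"sensitivity": sens, "specificity": spec}[oname])
            if fallback_key is None or fkey > fallback_key:
                fallback_key, fallback = fkey, (c, fl)
        if best is not None:
            c, flag = best
        elif cname == "npv":
            c, flag = fallback
        else:
            c = None  # step skipped
        chosen.append(c)
    ppv, npv, sens, spec = _evaluate_combo(flag, wcase, wctrl)
    cval = {"ppv": ppv, "npv": npv, "sensitivity": sens, "specificity": spec}[cname]
    if pv_target > 0 and (np.isnan(cval) or cval < pv_target):
        return None
    return chosen


def build_score_model(
    table: pd.DataFrame,
    labels: np.ndarray,
    predictors: list[str],
    objective: str,
    weights: np.ndarray | None = None,
    pv_target: float = 0.05,
    max_grid: int = 200,
) -> PartitionModel:
    """Single-threshold model on a predictor or a full-data PLS-DA score.

    Used for the non-partition rows of the model suite: the cut-off on the
    (oriented) score is chosen under the same predictive-value constraint
    and objective as the partition models.
    """
    labels = np.asarray(labels, dtype=bool)
    if len(predictors) == 1:
        vals = table[predictors[0]].to_numpy(dtype=float)
        step = PartitionStep(predictors, _risk_direction(predictors[0], vals, labels), None)
    else:
        scorer = fit_plsda(table, predictors, labels)
        step = PartitionStep(predictors, "up", None, scorer)
    w = np.ones(len(labels)) if weights is None else np.asarray(weights, dtype=float)
    cname, oname = _constraint_and_objective(objective)
    sc = step.score(table)
    cd = _candidates(sc, max_grid)
    chosen = _search_exhaustive([step], [sc], [cd], w * labels, w * (~labels), pv_target, cname, oname)
    model = PartitionModel([step], objective, pv_target)
    if chosen is None:
        model.feasible = False
        model.reason = f"no cut-off reaches weighted {cname} >= {pv_target}"
        return model
    step.cutoff = chosen[0]
    flag = step.flags(sc)
    ppv, npv, sens, spec = _evaluate_combo(flag, w * labels, w * (~labels))
    model.training_metrics = {"ppv": ppv, "npv": npv, "sensitivity": sens, "specificity": spec}
    return model


# ---------------------------------------------------------------------------
# model suite enumeration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    name: str
    method: str  # "score" (single/PLS-DA threshold) or "partition"
    predictors: tuple[str, ...]
    steps: tuple[tuple[str, ...], ...] = ()
    comparator: bool = False
    reference: bool = False


def _partition_layouts(combo: tuple[str, ...]) -> list[tuple[tuple[str, ...], ...]]:
    """All PlGF-first step layouts for a predictor combination."""
    others = [p for p in combo if p != PLGF]
    layouts = []
    if not others:
        return layouts
    if len(others) == 1:
        layouts.append(((PLGF,), (others[0],)))
    elif len(others) == 2:
        a, b = others
        layouts.append(((PLGF,), (a,), (b,)))
        layouts.append(((PLGF,), (b,), (a,)))
        layouts.append(((PLGF,), (a, b)))
    return layouts


def enumerate_models(pool: list[str], methods: tuple[str, ...] = ("score", "partition")) -> list[ModelSpec]:
    """All 1-3 predictor combinations crossed with the model methods.

    Partition models require PlGF in the combination (imposed first split).
    Combinations drawn solely from {PlGF, MAP, BMI} are tagged as comparator
    models.
    """
    comparator_pool = {PLGF, "MAP", "BMI"}
    specs: list[ModelSpec] = []
    for r in (1, 2, 3):
        for combo in combinations(pool, r):
            is_comp = set(combo) <= comparator_pool
            if "score" in methods:
                specs.append(
                    ModelSpec("+".join(combo), "score", combo, comparator=is_comp)
                )
            if "partition" in methods and PLGF in combo:
                for layout in _partition_layouts(combo):
                    name = "||".join(
                        step[0] if len(step) == 1 else "(" + "+".join(step) + ")"
                        for step in layout
                    )
                    specs.append(
                        ModelSpec(name, "partition", combo, steps=layout, comparator=is_comp)
                    )
    return specs


def table3_models() -> list[ModelSpec]:
    """The eight named models of the headline comparison, per objective."""
    return [
        ModelSpec(PLGF, "score", (PLGF,), reference=True),
        ModelSpec("DLG", "score", ("DLG",)),
        ModelSpec("PlGF+DLG", "score", (PLGF, "DLG"), reference=True),
        ModelSpec("PlGF+DLG+1-HGP", "score", (PLGF, "DLG", "1-HGP")),
        ModelSpec(
            "PlGF||MAP||BMI", "partition", (PLGF, "MAP", "BMI"),
            steps=((PLGF,), ("MAP",), ("BMI",)), comparator=True, reference=True,
        ),
        ModelSpec(
            "PlGF||DLG", "partition", (PLGF, "DLG"), steps=((PLGF,), ("DLG",)),
            reference=True,
        ),
        ModelSpec(
            "PlGF||(DLG+1-HGP)", "partition", (PLGF, "DLG", "1-HGP"),
            steps=((PLGF,), ("DLG", "1-HGP")),
        ),
        ModelSpec(
            "PlGF||DLG||1-HGP", "partition", (PLGF, "DLG", "1-HGP"),
            steps=((PLGF,), ("DLG",), ("1-HGP",)),
        ),
    ]


def fit_model_spec(
    spec: ModelSpec,
    table: pd.DataFrame,
    labels: np.ndarray,
    objective: str,
    weights: np.ndarray | None,
    pv_target: float,
    subgroup_labels: np.ndarray | None = None,
) -> PartitionModel:
    """Fit one suite entry under the given use-case objective."""
    if spec.method == "partition":
        return build_partition_model(
            table,
            labels,
            objective,
            [list(s) for s in spec.steps],
            weights=weights,
            pv_target=pv_target,
            subgroup_labels=subgroup_labels,
        )
    return build_score_model(
        table, labels, list(spec.predictors), objective, weights=weights, pv_target=pv_target
    )
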